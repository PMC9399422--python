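"""Candidate (putatively pathogenic) variant filtering.

A variant is a candidate when it is protein-altering AND either
(a) predicted deleterious (SIFT <= 0.05, inclusive) and rare in all three
population databases (1000 Genomes 2015aug_all, esp6500siv2_all and
ExAC_EAS, each < 0.05, strict), or (b) annotated pathogenic / likely
pathogenic in ClinVar.  Every decision carries a single reason code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import pandas as pd

from .io_core import (
    PROTEIN_ALTERING,
    AnnotatedVariant,
    ClinVarSig,
    FunctionalClass,
    VariantClass,
)


class FilterReason(str, Enum):
    """Why a variant passed or failed the candidate filter.

    Failure codes are assigned in gate order (class, then SIFT, then AF), so
    a variant violating exactly one clause receives that clause's code.
    """

    PASS_DELETERIOUS_RARE = "pass_deleterious_rare"
    PASS_CLINVAR = "pass_clinvar"
    FAIL_CLASS = "fail_class"
    FAIL_SIFT = "fail_sift"
    FAIL_AF = "fail_af"

    @property
    def passed(self) -> bool:
        return self.value.startswith("pass")


@dataclass
class FilterConfig:
    """Thresholds and missing-data policies of the candidate filter.

    ``missing_af_policy``: a variant absent from a population database is
    treated as rare by default (an unobserved allele cannot be common).
    ``missing_sift_policy_indel``: SIFT is undefined for most indels, so
    indels with no SIFT score are exempted from the deleteriousness test by
    default and qualify on class + rarity (or ClinVar) alone.
    ``clinvar_rescue_independent``: when True (default) the ClinVar route
    bypasses both SIFT and rarity; when False it substitutes for rarity
    only, i.e. the variant must still be deleterious.
    """

    sift_max: float = 0.05
    af_max: float = 0.05
    protein_altering_classes: frozenset[FunctionalClass] = PROTEIN_ALTERING
    clinvar_rescue: frozenset[ClinVarSig] = frozenset(
        {ClinVarSig.PATHOGENIC, ClinVarSig.LIKELY_PATHOGENIC}
    )
    missing_af_policy: str = "treat_as_rare"  # or "treat_as_fail"
    missing_sift_policy_indel: str = "exempt"  # or "fail"
    clinvar_requires_class: bool = True
    clinvar_rescue_independent: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.sift_max <= 1.0):
            raise ValueError(f"sift_max {self.sift_max} outside [0, 1]")
        if not (0.0 <= self.af_max <= 1.0):
            raise ValueError(f"af_max {self.af_max} outside [0, 1]")
        if self.missing_af_policy not in {"treat_as_rare", "treat_as_fail"}:
            raise ValueError(f"bad missing_af_policy {self.missing_af_policy!r}")
        if self.missing_sift_policy_indel not in {"exempt", "fail"}:
            raise ValueError(
                f"bad missing_sift_policy_indel {self.missing_sift_policy_indel!r}"
            )
        self.protein_altering_classes = frozenset(self.protein_altering_classes)
        self.clinvar_rescue = frozenset(self.clinvar_rescue)


def _deleterious(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    if v.sift is not None:
        return v.sift <= cfg.sift_max
    if v.variant_class is VariantClass.INDEL:
        return cfg.missing_sift_policy_indel == "exempt"
    return False  # SNP with no SIFT score fails the deleteriousness test


def _rare(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    missing_ok = cfg.missing_af_policy == "treat_as_rare"
    for af in (v.af_1000g, v.af_esp6500, v.af_exac_eas):
        if af is None:
            if not missing_ok:
                return False
        elif af >= cfg.af_max:
            return False
    return True


def is_candidate(
    v: AnnotatedVariant, cfg: FilterConfig | None = None
) -> tuple[bool, FilterReason]:
    """Decide whether one variant is a candidate, with a reason code."""
    cfg = cfg or FilterConfig()
    in_class = v.functional_class in cfg.protein_altering_classes
    clinvar_hit = v.clinvar in cfg.clinvar_rescue

    if cfg.clinvar_rescue_independent:
        if clinvar_hit and (in_class or not cfg.clinvar_requires_class):
            return True, FilterReason.PASS_CLINVAR
        if not in_class:
            return False, FilterReason.FAIL_CLASS
        if not _deleterious(v, cfg):
            return False, FilterReason.FAIL_SIFT
        if not _rare(v, cfg):
            return False, FilterReason.FAIL_AF
        return True, FilterReason.PASS_DELETERIOUS_RARE
    # alternative precedence: deleterious AND (rare OR clinvar)
    if not in_class:
        return False, FilterReason.FAIL_CLASS
    if not _deleterious(v, cfg):
        return False, FilterReason.FAIL_SIFT
    if _rare(v, cfg):
        return True, FilterReason.PASS_DELETERIOUS_RARE
    if clinvar_hit:
        return True, FilterReason.PASS_CLINVAR
    return False, FilterReason.FAIL_AF


@dataclass
class FilterSummary:
    """Candidate counts split by variant class, overall and per sample."""

    n_input: int
    n_candidates: int
    candidate_counts: dict[VariantClass, int]
    per_sample: pd.DataFrame  # index sample_id, columns SNP / INDEL / total
    reasons: list[FilterReason] = field(repr=False, default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return self.per_sample


def filter_cohort(
    variants: Sequence[AnnotatedVariant], cfg: FilterConfig | None = None
) -> tuple[list[AnnotatedVariant], FilterSummary]:
    """Apply the candidate filter to a cohort's variants.

    Returns the passing variants in their original order plus a summary with
    per-sample SNP/indel candidate counts and one reason code per input
    variant (aligned with the input order).
    """
    cfg = cfg or FilterConfig()
    candidates: list[AnnotatedVariant] = []
    reasons: list[FilterReason] = []
    rows: dict[str, dict[str, int]] = {}
    for v in variants:
        rows.setdefault(v.sample_id, {"SNP": 0, "INDEL": 0})
        ok, reason = is_candidate(v, cfg)
        reasons.append(reason)
        if ok:
            candidates.append(v)
            rows[v.sample_id][v.variant_class.value] += 1
    per_sample = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    if per_sample.empty:
        per_sample = pd.DataFrame(columns=["SNP", "INDEL"], dtype=int)
    per_sample["total"] = per_sample.get("SNP", 0) + per_sample.get("INDEL", 0)
    per_sample.index.name = "sample_id"
    counts = {
        VariantClass.SNP: sum(1 for c in candidates if c.variant_class is VariantClass.SNP),
        VariantClass.INDEL: sum(
            1 for c in candidates if c.variant_class is VariantClass.INDEL
        ),
    }
    summary = FilterSummary(
        n_input=len(variants),
        n_candidates=len(candidates),
        candidate_counts=counts,
        per_sample=per_sample,
        reasons=reasons,
    )
    return candidates, summary
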
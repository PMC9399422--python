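"""Cross-verification of exome-derived variants and gene panels.

Two uses, mirroring the study design: (1) same-patient RNA-seq variant
calls verify individual WES variants by exact (chrom, pos, ref, alt) key
match, sample by sample; (2) external cohorts' mutated-gene sets verify a
DMG panel at the gene level, ignoring sample identity.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_core import AnnotatedVariant, VariantClass, VariantKey


@dataclass
class RnaVariantSet:
    """Variant keys called from one sample's RNA-seq reads."""

    sample_id: str
    keys: frozenset[VariantKey]

    @classmethod
    def from_tuples(
        cls, sample_id: str, tuples: Iterable[tuple[str, int, str, str]]
    ) -> "RnaVariantSet":
        return cls(
            sample_id,
            frozenset(VariantKey.normalized(c, p, r, a) for c, p, r, a in tuples),
        )


def read_rna_variants(path: str | Path, sample_id: str) -> RnaVariantSet:
    """Read a 4-column (chrom, pos, ref, alt) TSV of RNA-seq variant calls.

    A header line starting with "chrom" is skipped.
    """
    keys: set[VariantKey] = set()
    with open(path, newline="") as fh:
        for line_no, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or not row[0].strip():
                continue
            if line_no == 1 and row[0].lower() in {"chrom", "chr", "#chrom"}:
                continue
            if len(row) < 4:
                raise ValueError(f"{path}: line {line_no}: expected 4 columns")
            keys.add(VariantKey.normalized(row[0], int(row[1]), row[2], row[3]))
    return RnaVariantSet(sample_id, frozenset(keys))


@dataclass
class VerificationReport:
    """Per-sample WES/RNA overlap counts and gene-panel verification."""

    per_sample: pd.DataFrame  # sample_id, snp_overlap, indel_overlap, wes_total, rna_total
    verified_keys: frozenset[tuple[str, VariantKey]] = field(repr=False)
    verified_genes: frozenset[str] = frozenset()

    @property
    def snp_overlap(self) -> int:
        return int(self.per_sample["snp_overlap"].sum())

    @property
    def indel_overlap(self) -> int:
        return int(self.per_sample["indel_overlap"].sum())

    @property
    def verification_rate(self) -> float:
        total = int(self.per_sample["wes_total"].sum())
        verified = self.snp_overlap + self.indel_overlap
        return verified / total if total else 0.0


def overlap_variants(
    wes: Sequence[AnnotatedVariant],
    rna_sets: Sequence[RnaVariantSet],
    match_samples: bool = True,
) -> VerificationReport:
    """Count WES variants whose key reappears among RNA-seq calls.

    With ``match_samples`` (the default, for same-patient verification) a
    WES variant must be found in its own sample's RNA set; without it, any
    sample's RNA set counts (for external cohorts).
    """
    by_sample: dict[str, frozenset[VariantKey]] = {
        r.sample_id: r.keys for r in rna_sets
    }
    pooled: frozenset[VariantKey] = frozenset().union(*by_sample.values()) if by_sample else frozenset()
    rows: dict[str, dict[str, int]] = {}
    verified: set[tuple[str, VariantKey]] = set()
    for v in wes:
        row = rows.setdefault(
            v.sample_id,
            {"snp_overlap": 0, "indel_overlap": 0, "wes_total": 0, "rna_total": 0},
        )
        row["wes_total"] += 1
        hit_set = by_sample.get(v.sample_id, frozenset()) if match_samples else pooled
        if v.key in hit_set:
            verified.add((v.sample_id, v.key))
            col = "snp_overlap" if v.variant_class is VariantClass.SNP else "indel_overlap"
            row[col] += 1
    for sid, row in rows.items():
        row["rna_total"] = len(by_sample.get(sid, frozenset())) if match_samples else len(pooled)
    per_sample = pd.DataFrame.from_dict(rows, orient="index")
    if per_sample.empty:
        per_sample = pd.DataFrame(
            columns=["snp_overlap", "indel_overlap", "wes_total", "rna_total"],
            dtype=int,
        )
    per_sample.index.name = "sample_id"
    return VerificationReport(per_sample=per_sample, verified_keys=frozenset(verified))


def verify_gene_panel(
    panel: set[str],
    candidates: Sequence[AnnotatedVariant],
    rna_sets: Sequence[RnaVariantSet],
    match_samples: bool = True,
) -> set[str]:
    """Genes of the panel with >= 1 RNA-verified candidate variant in >= 1
    sample.  Always a subset of the panel."""
    if not panel:
        raise ValueError("empty gene panel")
    in_panel = [v for v in candidates if v.gene in panel]
    report = overlap_variants(in_panel, rna_sets, match_samples=match_samples)
    verified_keys = {key for _, key in report.verified_keys}
    if match_samples:
        return {
            v.gene for v in in_panel if (v.sample_id, v.key) in report.verified_keys
        }
    return {v.gene for v in in_panel if v.key in verified_keys}


def external_gene_overlap(
    panel: set[str], external_sets: Mapping[str, set[str]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intersect a gene panel with named external mutated-gene sets.

    Returns ``(table, membership)``: per-set intersection sizes and member
    lists (plus union/intersection rows over all external sets), and an
    UpSet-style boolean membership matrix over the panel genes, both in
    deterministic sorted order.
    """
    names = sorted(external_sets)
    rows = []
    for name in names:
        inter = sorted(panel & external_sets[name])
        rows.append({"set": name, "n_overlap": len(inter), "genes": ",".join(inter)})
    if names:
        union_all = set().union(*(external_sets[n] for n in names))
        inter_all = set.intersection(*(set(external_sets[n]) for n in names))
        for label, s in (("UNION", union_all), ("INTERSECTION", inter_all)):
            inter = sorted(panel & s)
            rows.append({"set": label, "n_overlap": len(inter), "genes": ",".join(inter)})
    table = pd.DataFrame(rows, columns=["set", "n_overlap", "genes"])
    membership = pd.DataFrame(
        {name: [g in external_sets[name] for g in sorted(panel)] for name in names},
        index=sorted(panel),
    )
    membership.index.name = "gene"
    return table, membership
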
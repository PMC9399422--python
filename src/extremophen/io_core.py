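"""Shared domain types and readers/writers for the pipeline's tabular formats.

The pipeline consumes per-sample annotated variant tables (ANNOVAR-style TSV
or annotated VCF), a two-column cohort design file, per-gene expression
statistics, and plain gene lists.  All coordinates are 1-based and fully
closed (VCF convention); indels are taken as given, with no re-alignment
beyond splitting multi-allelic VCF records.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

MISSING_SENTINELS = {".", "", "NA", "na", "nan"}


class VariantClass(str, Enum):
    SNP = "SNP"
    INDEL = "INDEL"


class FunctionalClass(str, Enum):
    NONSYNONYMOUS_SNV = "nonsynonymous_SNV"
    MISSENSE = "missense"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    FRAMESHIFT_INSERTION = "frameshift_insertion"
    FRAMESHIFT_DELETION = "frameshift_deletion"
    NONFRAMESHIFT_INDEL = "nonframeshift_indel"
    SYNONYMOUS_SNV = "synonymous_SNV"
    OTHER = "other"


#: Functional classes that alter the protein product; the candidate filter
#: is scoped to these.
PROTEIN_ALTERING: frozenset[FunctionalClass] = frozenset(
    {
        FunctionalClass.NONSYNONYMOUS_SNV,
        FunctionalClass.MISSENSE,
        FunctionalClass.STOPGAIN,
        FunctionalClass.STOPLOSS,
        FunctionalClass.FRAMESHIFT_INSERTION,
        FunctionalClass.FRAMESHIFT_DELETION,
        FunctionalClass.NONFRAMESHIFT_INDEL,
    }
)


class ClinVarSig(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    VUS = "vus"
    ABSENT = "absent"


_FUNC_ALIASES: dict[str, FunctionalClass] = {
    "nonsynonymous_snv": FunctionalClass.NONSYNONYMOUS_SNV,
    "missense": FunctionalClass.MISSENSE,
    "missense_variant": FunctionalClass.MISSENSE,
    "stopgain": FunctionalClass.STOPGAIN,
    "stop_gained": FunctionalClass.STOPGAIN,
    "stoploss": FunctionalClass.STOPLOSS,
    "stop_lost": FunctionalClass.STOPLOSS,
    "frameshift_insertion": FunctionalClass.FRAMESHIFT_INSERTION,
    "frameshift_deletion": FunctionalClass.FRAMESHIFT_DELETION,
    "nonframeshift_indel": FunctionalClass.NONFRAMESHIFT_INDEL,
    "nonframeshift_insertion": FunctionalClass.NONFRAMESHIFT_INDEL,
    "nonframeshift_deletion": FunctionalClass.NONFRAMESHIFT_INDEL,
    "synonymous_snv": FunctionalClass.SYNONYMOUS_SNV,
    "other": FunctionalClass.OTHER,
}

_CLINVAR_ALIASES: dict[str, ClinVarSig] = {
    "pathogenic": ClinVarSig.PATHOGENIC,
    "pathogenic/likely_pathogenic": ClinVarSig.PATHOGENIC,
    "likely_pathogenic": ClinVarSig.LIKELY_PATHOGENIC,
    "benign": ClinVarSig.BENIGN,
    "benign/likely_benign": ClinVarSig.BENIGN,
    "likely_benign": ClinVarSig.LIKELY_BENIGN,
    "uncertain_significance": ClinVarSig.VUS,
    "vus": ClinVarSig.VUS,
    "absent": ClinVarSig.ABSENT,
}


def parse_functional_class(raw: str) -> FunctionalClass:
    """Map an annotation string to a functional class.

    Matching is case-insensitive with spaces treated as underscores.
    Unknown strings map to ``other`` with a logged warning.
    """
    key = raw.strip().lower().replace(" ", "_")
    if key in MISSING_SENTINELS:
        return FunctionalClass.OTHER
    cls = _FUNC_ALIASES.get(key)
    if cls is None:
        logger.warning("unknown functional class %r mapped to 'other'", raw)
        return FunctionalClass.OTHER
    return cls


def parse_clinvar(raw: str) -> ClinVarSig:
    """Map a ClinVar clinical-significance string, case-insensitively.

    Combined "Pathogenic/Likely_pathogenic" assertions map to pathogenic;
    missing sentinels map to absent; other unrecognised non-missing strings
    (conflicting interpretations, drug response, ...) map to vus.
    """
    key = raw.strip().lower().replace(" ", "_")
    if key in MISSING_SENTINELS:
        return ClinVarSig.ABSENT
    sig = _CLINVAR_ALIASES.get(key)
    if sig is None:
        logger.warning("unrecognised ClinVar significance %r mapped to 'vus'", raw)
        return ClinVarSig.VUS
    return sig


def classify_alleles(ref: str, alt: str) -> VariantClass:
    """SNP iff both alleles are single bases (ANNOVAR's '-' marks an indel)."""
    if len(ref) == 1 and len(alt) == 1 and ref != "-" and alt != "-":
        return VariantClass.SNP
    return VariantClass.INDEL


@dataclass(frozen=True)
class VariantKey:
    """Cross-platform variant identity: (chrom, pos, ref, alt).

    Keys are normalized — "chr" prefix stripped, alleles upper-cased — so
    exome- and RNA-seq-derived calls of the same event compare equal.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    @classmethod
    def normalized(cls, chrom: str, pos: int, ref: str, alt: str) -> "VariantKey":
        c = chrom[3:] if chrom.lower().startswith("chr") else chrom
        return cls(c, int(pos), ref.upper(), alt.upper())

    def __str__(self) -> str:  # used in provenance TSVs
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @classmethod
    def parse(cls, s: str) -> "VariantKey":
        chrom, pos, alleles = s.split(":")
        ref, alt = alleles.split(">")
        return cls.normalized(chrom, int(pos), ref, alt)


@dataclass
class AnnotatedVariant:
    """One variant call in one sample with its annotations.

    ``sift`` and the three population allele frequencies may be None
    (annotation absent).  ``variant_class`` is derived from the alleles.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    functional_class: FunctionalClass
    gene: str
    sift: float | None = None
    af_1000g: float | None = None
    af_esp6500: float | None = None
    af_exac_eas: float | None = None
    clinvar: ClinVarSig = ClinVarSig.ABSENT
    variant_class: VariantClass = field(init=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        for name in ("sift", "af_1000g", "af_esp6500", "af_exac_eas"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        self.variant_class = classify_alleles(self.ref, self.alt)

    @property
    def key(self) -> VariantKey:
        return VariantKey.normalized(self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class CohortDesign:
    """Ordered assignment of samples to phenotype groups.

    Group labels are arbitrary; the reference cohort layout is DM (diabetes,
    no retinopathy), DR (early-onset retinopathy) and DM-DR (late-onset
    retinopathy).
    """

    groups: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for label, sample_ids in self.groups:
            if not sample_ids:
                raise ValueError(f"group {label!r} is empty")
            for s in sample_ids:
                if s in seen:
                    raise ValueError(
                        f"sample {s!r} assigned to both {seen[s]!r} and {label!r}"
                    )
                seen[s] = label

    @classmethod
    def from_items(cls, items: Iterable[tuple[str, Sequence[str]]]) -> "CohortDesign":
        return cls(tuple((lab, tuple(ss)) for lab, ss in items))

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.groups]

    @property
    def samples(self) -> list[str]:
        return [s for _, ss in self.groups for s in ss]

    def group_samples(self, label: str) -> tuple[str, ...]:
        for lab, ss in self.groups:
            if lab == label:
                return ss
        raise KeyError(label)

    def group_of(self, sample_id: str) -> str:
        for lab, ss in self.groups:
            if sample_id in ss:
                return lab
        raise KeyError(sample_id)

    def sizes(self) -> dict[str, int]:
        return {lab: len(ss) for lab, ss in self.groups}


@dataclass(frozen=True)
class ExpressionStat:
    """Per-gene differential-expression statistic (ratio-scale fold change)."""

    gene: str
    fold_change: float
    p_value: float

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError(f"fold_change must be > 0, got {self.fold_change}")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# ANNOVAR-style TSV dialect
# ---------------------------------------------------------------------------

#: Required columns of the annovar_tsv dialect (extra columns are ignored).
ANNOVAR_COLUMNS = [
    "Chr",
    "Start",
    "Ref",
    "Alt",
    "Gene.refGene",
    "ExonicFunc.refGene",
    "SIFT_score",
    "1000g2015aug_all",
    "esp6500siv2_all",
    "ExAC_EAS",
    "CLNSIG",
]


class VariantParseError(ValueError):
    """Malformed variant table; message names the offending line."""


def _parse_optional_float(raw: str, *, line_no: int, col: str) -> float | None:
    if raw.strip() in MISSING_SENTINELS:
        return None
    try:
        return float(raw)
    except ValueError as exc:
        raise VariantParseError(f"line {line_no}: bad number in {col}: {raw!r}") from exc


def _read_annovar_tsv(path: Path, sample_id: str) -> list[AnnotatedVariant]:
    out: list[AnnotatedVariant] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise VariantParseError(f"line 1: {path} is empty (no header)")
        missing = [c for c in ANNOVAR_COLUMNS if c not in header]
        if missing:
            raise VariantParseError(f"line 1: missing required columns {missing}")
        idx = {c: header.index(c) for c in ANNOVAR_COLUMNS}
        for line_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < len(header):
                raise VariantParseError(
                    f"line {line_no}: expected {len(header)} fields, got {len(row)}"
                )
            try:
                pos = int(row[idx["Start"]])
            except ValueError as exc:
                raise VariantParseError(
                    f"line {line_no}: bad position {row[idx['Start']]!r}"
                ) from exc
            out.append(
                AnnotatedVariant(
                    sample_id=sample_id,
                    chrom=row[idx["Chr"]],
                    pos=pos,
                    ref=row[idx["Ref"]],
                    alt=row[idx["Alt"]],
                    functional_class=parse_functional_class(row[idx["ExonicFunc.refGene"]]),
                    gene=row[idx["Gene.refGene"]],
                    sift=_parse_optional_float(
                        row[idx["SIFT_score"]], line_no=line_no, col="SIFT_score"
                    ),
                    af_1000g=_parse_optional_float(
                        row[idx["1000g2015aug_all"]], line_no=line_no, col="1000g2015aug_all"
                    ),
                    af_esp6500=_parse_optional_float(
                        row[idx["esp6500siv2_all"]], line_no=line_no, col="esp6500siv2_all"
                    ),
                    af_exac_eas=_parse_optional_float(
                        row[idx["ExAC_EAS"]], line_no=line_no, col="ExAC_EAS"
                    ),
                    clinvar=parse_clinvar(row[idx["CLNSIG"]]),
                )
            )
    return out


#: Default INFO keys for the VCF dialect; override via ``info_keys``.
DEFAULT_VCF_INFO_KEYS: dict[str, str] = {
    "gene": "Gene",
    "functional_class": "ExonicFunc",
    "sift": "SIFT",
    "af_1000g": "AF_1000G",
    "af_esp6500": "AF_ESP6500",
    "af_exac_eas": "AF_EXAC_EAS",
    "clinvar": "CLNSIG",
}


def _info_per_alt(value: object, i: int, n_alt: int) -> str:
    """Extract the i-th alternate allele's value from an INFO field."""
    if value is None:
        return "."
    if isinstance(value, (tuple, list)):
        return "." if i >= len(value) or value[i] is None else str(value[i])
    s = str(value)
    parts = s.split(",")
    if len(parts) == n_alt:
        return parts[i]
    return s  # shared across alleles


def _read_vcf(
    path: Path, sample_id: str, info_keys: Mapping[str, str]
) -> list[AnnotatedVariant]:
    from cyvcf2 import VCF

    out: list[AnnotatedVariant] = []
    vcf = VCF(str(path))
    try:
        for rec in vcf:
            alts = rec.ALT or []
            for i, alt in enumerate(alts):
                info = {
                    field: _info_per_alt(rec.INFO.get(key), i, len(alts))
                    for field, key in info_keys.items()
                }
                out.append(
                    AnnotatedVariant(
                        sample_id=sample_id,
                        chrom=rec.CHROM,
                        pos=rec.POS,
                        ref=rec.REF,
                        alt=alt,
                        functional_class=parse_functional_class(info["functional_class"]),
                        gene=info["gene"],
                        sift=_parse_optional_float(info["sift"], line_no=-1, col="SIFT"),
                        af_1000g=_parse_optional_float(
                            info["af_1000g"], line_no=-1, col="af_1000g"
                        ),
                        af_esp6500=_parse_optional_float(
                            info["af_esp6500"], line_no=-1, col="af_esp6500"
                        ),
                        af_exac_eas=_parse_optional_float(
                            info["af_exac_eas"], line_no=-1, col="af_exac_eas"
                        ),
                        clinvar=parse_clinvar(info["clinvar"]),
                    )
                )
    finally:
        vcf.close()
    return out


def read_variant_table(
    path: str | Path,
    sample_id: str,
    dialect: str = "annovar_tsv",
    info_keys: Mapping[str, str] | None = None,
) -> list[AnnotatedVariant]:
    """Read one sample's annotated variants.

    Parameters
    ----------
    path
        Variant table path.
    sample_id
        Sample the calls belong to (annotated on every record).
    dialect
        ``annovar_tsv`` (tab-separated with the ANNOVAR column names in
        :data:`ANNOVAR_COLUMNS`) or ``vcf`` (annotations read from INFO
        keys, default :data:`DEFAULT_VCF_INFO_KEYS`).  Multi-allelic VCF
        records are split into one variant per alternate allele.
    """
    path = Path(path)
    if dialect == "annovar_tsv":
        return _read_annovar_tsv(path, sample_id)
    if dialect == "vcf":
        return _read_vcf(path, sample_id, info_keys or DEFAULT_VCF_INFO_KEYS)
    raise ValueError(f"unknown dialect {dialect!r}")


def _fmt_optional(v: float | None) -> str:
    return "." if v is None else repr(v)


def write_variant_table(variants: Sequence[AnnotatedVariant], path: str | Path) -> None:
    """Write variants in the annovar_tsv dialect (plus a sample_id column).

    Round-trips losslessly with :func:`read_variant_table`: absent values
    are written as "." and floats with full precision.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id"] + ANNOVAR_COLUMNS)
        for v in variants:
            w.writerow(
                [
                    v.sample_id,
                    v.chrom,
                    v.pos,
                    v.ref,
                    v.alt,
                    v.gene,
                    v.functional_class.value,
                    _fmt_optional(v.sift),
                    _fmt_optional(v.af_1000g),
                    _fmt_optional(v.af_esp6500),
                    _fmt_optional(v.af_exac_eas),
                    "." if v.clinvar is ClinVarSig.ABSENT else v.clinvar.value,
                ]
            )


def read_cohort_variant_table(path: str | Path) -> list[AnnotatedVariant]:
    """Read a multi-sample table written by :func:`write_variant_table`."""
    out: list[AnnotatedVariant] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[0] != "sample_id":
            raise VariantParseError("line 1: first column must be sample_id")
        idx = {c: header.index(c) for c in ANNOVAR_COLUMNS}
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            out.append(
                AnnotatedVariant(
                    sample_id=row[0],
                    chrom=row[idx["Chr"]],
                    pos=int(row[idx["Start"]]),
                    ref=row[idx["Ref"]],
                    alt=row[idx["Alt"]],
                    functional_class=parse_functional_class(row[idx["ExonicFunc.refGene"]]),
                    gene=row[idx["Gene.refGene"]],
                    sift=_parse_optional_float(row[idx["SIFT_score"]], line_no=line_no, col="SIFT_score"),
                    af_1000g=_parse_optional_float(row[idx["1000g2015aug_all"]], line_no=line_no, col="1000g2015aug_all"),
                    af_esp6500=_parse_optional_float(row[idx["esp6500siv2_all"]], line_no=line_no, col="esp6500siv2_all"),
                    af_exac_eas=_parse_optional_float(row[idx["ExAC_EAS"]], line_no=line_no, col="ExAC_EAS"),
                    clinvar=parse_clinvar(row[idx["CLNSIG"]]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Cohort design
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> CohortDesign:
    """Read a two-column ``sample_id<TAB>group`` design file.

    Groups appear in first-appearance order.  A header line reading
    ``sample_id<TAB>group`` is skipped.  A sample assigned twice is an error.
    """
    order: list[str] = []
    members: dict[str, list[str]] = {}
    with open(path, newline="") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise VariantParseError(
                    f"line {line_no}: expected 2 tab-separated fields, got {len(parts)}"
                )
            sample, group = parts[0].strip(), parts[1].strip()
            if line_no == 1 and (sample, group) == ("sample_id", "group"):
                continue
            if group not in members:
                order.append(group)
                members[group] = []
            members[group].append(sample)
    if not order:
        raise VariantParseError("design file defines no samples")
    return CohortDesign.from_items((g, members[g]) for g in order)


def write_design(design: CohortDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for label, samples in design.groups:
            for s in samples:
                fh.write(f"{s}\t{label}\n")


def read_expression_stats(path: str | Path) -> list[ExpressionStat]:
    """Read a gene/fold_change/p_value TSV (externally computed DE stats)."""
    out: list[ExpressionStat] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                ExpressionStat(
                    gene=row["gene"],
                    fold_change=float(row["fold_change"]),
                    p_value=float(row["p_value"]),
                )
            )
    return out


def read_gene_set(path: str | Path) -> set[str]:
    """Read a one-symbol-per-line gene list."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
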
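"""Synthetic extreme-phenotype cohorts with planted, fully known structure.

The generator emulates the data the real pipeline consumes — per-sample
annotated exome variant tables, RNA-seq variant subsets, expression counts
and external gene sets — for a three-group cohort (retinopathy-free
diabetics, early-onset and late-onset retinopathy; default sizes 6/5/4).

Planted differentially mutated genes use exact-count carrier assignment
(rate x group size must be an integer), so intended per-group rates are
realised exactly and threshold behaviour is not confounded by sampling
noise; background genes use Bernoulli draws.  Decoy variants each violate
exactly one filter clause (functional class, SIFT, or allele frequency), so
every filter reason code is exercised and attributable.  Every artifact
draws from its own labelled pseudo-random stream derived from the master
seed, so adding an artifact never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .crossval import RnaVariantSet
from .io_core import (
    AnnotatedVariant,
    ClinVarSig,
    CohortDesign,
    FunctionalClass,
)

_BASES = ("A", "C", "G", "T")

# stable label -> stream index for sub-seeding; append only
_STREAMS = {"wes": 0, "rna": 1, "counts": 2, "external": 3}


def _rng(seed: int, label: str) -> np.random.Generator:
    """Independent generator for one artifact, derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[label],))
    )


@dataclass(frozen=True)
class PlantedDMG:
    """A gene planted with fixed per-group carrier rates."""

    gene: str
    rates: tuple[tuple[str, float], ...]  # (group label, carrier rate)

    def rate_of(self, group: str) -> float:
        for g, r in self.rates:
            if g == group:
                return r
        return 0.0


@dataclass(frozen=True)
class PlantedDEG:
    gene: str
    fold_change: float


@dataclass
class AnnotationModel:
    """How candidate and decoy annotations are drawn.

    Candidates satisfy every filter clause (a ``clinvar_rescue_fraction``
    of them only via the ClinVar route); decoys violate exactly one clause.
    """

    clinvar_rescue_fraction: float = 0.10
    af_missing_fraction: float = 0.20
    indel_fraction: float = 0.15

    def __post_init__(self) -> None:
        for name in ("clinvar_rescue_fraction", "af_missing_fraction", "indel_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class SyntheticCohortSpec:
    """Full parameterisation of one synthetic cohort.

    Defaults follow the reference study conditions: groups DM/DR/DM-DR of
    6/5/4 samples, a 5% per-gene per-sample background candidate-carrier
    rate, roughly one-third WES->RNA variant concordance, and
    moderate-dispersion negative-binomial expression counts.
    """

    seed: int = 0
    groups: tuple[tuple[str, int], ...] = (("DM", 6), ("DR", 5), ("DM-DR", 4))
    n_genes: int = 500
    background_candidate_rate: float = 0.05
    planted_dmgs: tuple[PlantedDMG, ...] = ()
    decoy_noncandidate_rate: float = 0.05
    mean_variants_per_hit: float = 1.3
    annotation: AnnotationModel = field(default_factory=AnnotationModel)
    rna_concordance: float = 0.33
    planted_degs: tuple[PlantedDEG, ...] = ()
    n_expression_genes: int = 2000
    baseline_mean: float = 100.0
    nb_dispersion: float = 0.1
    deg_case_group: str = "DR"
    deg_control_group: str = "DM"

    def __post_init__(self) -> None:
        for name in ("background_candidate_rate", "decoy_noncandidate_rate",
                     "rna_concordance"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.mean_variants_per_hit < 1.0:
            raise ValueError("mean_variants_per_hit must be >= 1")
        names = [p.gene for p in self.planted_dmgs]
        if len(names) != len(set(names)):
            raise ValueError("duplicate planted DMG gene names")
        labels = {g for g, _ in self.groups}
        for p in self.planted_dmgs:
            for g, _ in p.rates:
                if g not in labels:
                    raise KeyError(f"planted DMG {p.gene}: unknown group {g!r}")

    def design(self) -> CohortDesign:
        return CohortDesign.from_items(
            (label, [f"{label}_{i + 1:02d}" for i in range(n)])
            for label, n in self.groups
        )


@dataclass
class CohortTruth:
    """What was planted: intended DMG rates and per-variant filter outcome."""

    dmg_truth: pd.DataFrame  # gene, group, intended_rate, carriers
    variant_truth: pd.DataFrame  # sample_id, gene, variant_key, role, expected_reason


def _gene_locus(gene_index: int) -> tuple[str, int]:
    return str(1 + gene_index % 22), 1 + gene_index * 100_000


def _draw_snp_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[rng.integers(4)]
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return ref, alt


_CANDIDATE_SNP_CLASSES = (
    FunctionalClass.NONSYNONYMOUS_SNV,
    FunctionalClass.MISSENSE,
    FunctionalClass.STOPGAIN,
    FunctionalClass.STOPLOSS,
)
_CANDIDATE_INDEL_CLASSES = (
    FunctionalClass.FRAMESHIFT_INSERTION,
    FunctionalClass.FRAMESHIFT_DELETION,
    FunctionalClass.NONFRAMESHIFT_INDEL,
)


def _rare_afs(rng: np.random.Generator, model: AnnotationModel) -> list[float | None]:
    return [
        None if rng.random() < model.af_missing_fraction else float(rng.uniform(0, 0.049))
        for _ in range(3)
    ]


def _make_candidate(
    rng: np.random.Generator,
    sample_id: str,
    gene: str,
    gene_index: int,
    offset: int,
    model: AnnotationModel,
) -> AnnotatedVariant:
    chrom, base = _gene_locus(gene_index)
    pos = base + int(offset)
    afs = _rare_afs(rng, model)
    if rng.random() < model.indel_fraction:
        ref, _ = _draw_snp_alleles(rng)
        ins = _BASES[rng.integers(4)]
        if rng.random() < 0.5:
            ref, alt = ref, ref + ins  # insertion
        else:
            ref, alt = ref + ins, ref  # deletion
        return AnnotatedVariant(
            sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
            functional_class=_CANDIDATE_INDEL_CLASSES[rng.integers(3)],
            gene=gene, sift=None,
            af_1000g=afs[0], af_esp6500=afs[1], af_exac_eas=afs[2],
            clinvar=ClinVarSig.ABSENT,
        )
    ref, alt = _draw_snp_alleles(rng)
    if rng.random() < model.clinvar_rescue_fraction:
        sift = float(rng.uniform(0.2, 1.0))  # fails SIFT, rescued by ClinVar
        clinvar = (
            ClinVarSig.PATHOGENIC if rng.random() < 0.5 else ClinVarSig.LIKELY_PATHOGENIC
        )
    else:
        sift = float(rng.uniform(0, 0.05))
        clinvar = ClinVarSig.ABSENT
    return AnnotatedVariant(
        sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
        functional_class=_CANDIDATE_SNP_CLASSES[rng.integers(4)],
        gene=gene, sift=sift,
        af_1000g=afs[0], af_esp6500=afs[1], af_exac_eas=afs[2],
        clinvar=clinvar,
    )


def _make_decoy(
    rng: np.random.Generator,
    sample_id: str,
    gene: str,
    gene_index: int,
    offset: int,
    model: AnnotationModel,
) -> tuple[AnnotatedVariant, str]:
    """A variant violating exactly one filter clause; returns it with the
    expected failure reason code."""
    chrom, base = _gene_locus(gene_index)
    pos = base + int(offset)
    ref, alt = _draw_snp_alleles(rng)
    clause = ("class", "sift", "af")[rng.integers(3)]
    sift = float(rng.uniform(0, 0.05))
    afs: list[float | None] = [float(rng.uniform(0, 0.049)) for _ in range(3)]
    func = _CANDIDATE_SNP_CLASSES[rng.integers(4)]
    if clause == "class":
        func = FunctionalClass.SYNONYMOUS_SNV
        reason = "fail_class"
    elif clause == "sift":
        sift = float(rng.uniform(0.051, 1.0))
        reason = "fail_sift"
    else:
        afs[int(rng.integers(3))] = float(rng.uniform(0.05, 0.5))
        reason = "fail_af"
    v = AnnotatedVariant(
        sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
        functional_class=func, gene=gene, sift=sift,
        af_1000g=afs[0], af_esp6500=afs[1], af_exac_eas=afs[2],
        clinvar=ClinVarSig.ABSENT,
    )
    return v, reason


def _exact_carriers(rate: float, samples: Sequence[str], gene: str,
                    rng: np.random.Generator) -> list[str]:
    n = len(samples)
    k_float = rate * n
    k = round(k_float)
    if abs(k_float - k) > 1e-9:
        raise ValueError(
            f"planted gene {gene}: rate {rate} unrealizable at group size {n}"
        )
    idx = rng.choice(n, size=k, replace=False)
    return [samples[i] for i in sorted(idx)]


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[dict[str, list[AnnotatedVariant]], CohortDesign, CohortTruth]:
    """Generate per-sample annotated variant tables with known truth.

    Deterministic for a fixed spec (seed included).  Returns the tables
    keyed by sample, the cohort design, and the truth records.
    """
    rng = _rng(spec.seed, "wes")
    design = spec.design()
    planted_names = {p.gene for p in spec.planted_dmgs}
    background_genes = [f"GENE{i + 1:05d}" for i in range(spec.n_genes)]
    all_genes = sorted(planted_names) + background_genes
    gene_index = {g: i for i, g in enumerate(all_genes)}

    tables: dict[str, list[AnnotatedVariant]] = {s: [] for s in design.samples}
    dmg_rows = []
    var_rows = []

    def n_hits() -> int:
        return 1 + int(rng.poisson(spec.mean_variants_per_hit - 1.0))

    def add_candidates(sample: str, gene: str) -> None:
        k = n_hits()
        offsets = rng.choice(99_999, size=k, replace=False)
        for off in offsets:
            v = _make_candidate(rng, sample, gene, gene_index[gene], off, spec.annotation)
            tables[sample].append(v)
            var_rows.append(
                {"sample_id": sample, "gene": gene, "variant_key": str(v.key),
                 "role": "candidate",
                 "expected_reason": "pass_clinvar"
                 if v.clinvar in (ClinVarSig.PATHOGENIC, ClinVarSig.LIKELY_PATHOGENIC)
                 else "pass_deleterious_rare"}
            )

    # planted DMG carriers: exact counts per group
    for p in spec.planted_dmgs:
        for label, _ in spec.groups:
            rate = p.rate_of(label)
            carriers = _exact_carriers(rate, design.group_samples(label), p.gene, rng)
            dmg_rows.append(
                {"gene": p.gene, "group": label, "intended_rate": rate,
                 "carriers": len(carriers)}
            )
            for s in carriers:
                add_candidates(s, p.gene)

    # background carriers: Bernoulli per (gene, sample)
    for g in background_genes:
        for s in design.samples:
            if rng.random() < spec.background_candidate_rate:
                add_candidates(s, g)

    # decoys: background genes only, each violating exactly one clause
    for g in background_genes:
        for s in design.samples:
            if rng.random() < spec.decoy_noncandidate_rate:
                off = int(rng.integers(99_999))
                v, reason = _make_decoy(rng, s, g, gene_index[g], off, spec.annotation)
                tables[s].append(v)
                var_rows.append(
                    {"sample_id": s, "gene": g, "variant_key": str(v.key),
                     "role": "decoy", "expected_reason": reason}
                )

    truth = CohortTruth(
        dmg_truth=pd.DataFrame(
            dmg_rows, columns=["gene", "group", "intended_rate", "carriers"]
        ),
        variant_truth=pd.DataFrame(
            var_rows,
            columns=["sample_id", "gene", "variant_key", "role", "expected_reason"],
        ),
    )
    return tables, design, truth


def generate_rna_sets(
    wes_tables: Mapping[str, Sequence[AnnotatedVariant]],
    rna_concordance: float,
    seed: int,
    n_rna_only: int = 0,
) -> list[RnaVariantSet]:
    """RNA-seq variant subsets: each WES variant re-appears in its sample's
    RNA set independently with probability ``rna_concordance``; optionally
    ``n_rna_only`` decoy keys per sample that match nothing in WES."""
    if not (0.0 <= rna_concordance <= 1.0):
        raise ValueError("rna_concordance outside [0, 1]")
    rng = _rng(seed, "rna")
    out: list[RnaVariantSet] = []
    for sample in sorted(wes_tables):
        keys = {
            v.key for v in wes_tables[sample] if rng.random() < rna_concordance
        }
        for i in range(n_rna_only):
            ref, alt = _draw_snp_alleles(rng)
            # chrom "99" cannot collide with generated WES loci (chrom 1-22)
            keys.add(
                AnnotatedVariant(
                    sample_id=sample, chrom="99",
                    pos=int(rng.integers(1, 10**7)), ref=ref, alt=alt,
                    functional_class=FunctionalClass.OTHER, gene="RNAONLY",
                ).key
            )
        out.append(RnaVariantSet(sample, frozenset(keys)))
    return out


def generate_counts(
    spec: SyntheticCohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial gene x sample count matrix with planted DEGs.

    Counts have mean ``baseline_mean`` and variance m + dispersion * m^2;
    planted DEG genes scale the mean in ``deg_case_group`` samples by their
    fold change.  Returns the matrix and a truth table (gene, fold_change).
    """
    rng = _rng(spec.seed, "counts")
    design = spec.design()
    planted = {p.gene: p.fold_change for p in spec.planted_degs}
    genes = sorted(planted) + [
        f"EXPR{i + 1:05d}" for i in range(spec.n_expression_genes)
    ]
    samples = design.samples
    case = set(design.group_samples(spec.deg_case_group))
    fc_vec = np.array([planted.get(g, 1.0) for g in genes])
    case_mask = np.array([s in case for s in samples])
    means = spec.baseline_mean * np.where(case_mask[None, :], fc_vec[:, None], 1.0)
    if spec.nb_dispersion <= 0:
        mat = rng.poisson(means)
    else:
        size = 1.0 / spec.nb_dispersion
        p = size / (size + np.maximum(means, 1e-300))
        mat = rng.negative_binomial(size, p)
    mat = np.where(means <= 0, 0, mat).astype(np.int64)
    counts = pd.DataFrame(mat, index=genes, columns=samples)
    counts.index.name = "gene"
    truth = pd.DataFrame(
        [{"gene": g, "fold_change": fc} for g, fc in sorted(planted.items())],
        columns=["gene", "fold_change"],
    )
    return counts, truth


def demo_spec(seed: int = 0) -> SyntheticCohortSpec:
    """A default cohort with planted structure at the study's group sizes.

    Six susceptible genes (carriers concentrated in the retinopathy
    groups), two protective genes (carriers only in the retinopathy-free
    DM group), and five 8-fold upregulated DEGs, over a 500-gene exome
    background and 2,000 expression genes.
    """
    susceptible = tuple(
        PlantedDMG(f"SUSC{i + 1:02d}", (("DM", 0.0), ("DR", 1.0), ("DM-DR", rate)))
        for i, rate in enumerate((1.0, 1.0, 0.75, 0.25, 0.0, 0.0))
    )
    protective = tuple(
        PlantedDMG(f"PROT{i + 1:02d}", (("DM", 1.0), ("DR", 0.0), ("DM-DR", 0.25)))
        for i in range(2)
    )
    degs = tuple(PlantedDEG(f"UPGENE{i + 1:02d}", 8.0) for i in range(5))
    return SyntheticCohortSpec(
        seed=seed,
        planted_dmgs=susceptible + protective,
        planted_degs=degs,
    )


def write_cohort(spec: SyntheticCohortSpec, outdir) -> "Path":
    """Materialise a synthetic cohort on disk in the pipeline's input formats.

    Writes per-sample variant tables, the design file, RNA-seq variant
    subsets, the count matrix, the truth tables, and a ready-to-run
    ``run.yaml`` pipeline config.  Returns the output directory.
    """
    from pathlib import Path

    import yaml

    from .io_core import write_design, write_variant_table

    outdir = Path(outdir)
    (outdir / "variants").mkdir(parents=True, exist_ok=True)
    (outdir / "rna").mkdir(exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)

    tables, design, truth = generate_cohort(spec)
    write_design(design, outdir / "design.tsv")
    variant_paths: dict[str, str] = {}
    for sample in design.samples:
        p = outdir / "variants" / f"{sample}.tsv"
        write_variant_table(tables[sample], p)
        variant_paths[sample] = str(p)
    rna_sets = generate_rna_sets(tables, spec.rna_concordance, spec.seed)
    rna_paths: dict[str, str] = {}
    for rset in rna_sets:
        p = outdir / "rna" / f"{rset.sample_id}.tsv"
        with open(p, "w") as fh:
            fh.write("chrom\tpos\tref\talt\n")
            for key in sorted(rset.keys, key=lambda k: (k.chrom, k.pos, k.ref, k.alt)):
                fh.write(f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\n")
        rna_paths[rset.sample_id] = str(p)
    counts, deg_truth = generate_counts(spec)
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    truth.dmg_truth.to_csv(outdir / "truth" / "dmg_truth.tsv", sep="\t", index=False)
    truth.variant_truth.to_csv(
        outdir / "truth" / "variant_truth.tsv", sep="\t", index=False
    )
    deg_truth.to_csv(outdir / "truth" / "deg_truth.tsv", sep="\t", index=False)

    control = spec.groups[0][0]
    cfg = {
        "design": str(outdir / "design.tsv"),
        "variants": variant_paths,
        "control_group": control,
        "comparisons": [[g, control] for g, _ in spec.groups[1:]],
        "crossval": {"rna": rna_paths, "match_samples": True},
        "expression": {
            "counts": str(outdir / "counts.tsv"),
            "case_group": spec.deg_case_group,
            "control_group": spec.deg_control_group,
        },
    }
    with open(outdir / "run.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return outdir


def generate_external_sets(
    panel: Sequence[str],
    n_sets: int,
    hit_fraction: float,
    n_extra: int,
    seed: int,
) -> dict[str, set[str]]:
    """Named external mutated-gene sets: each contains a random
    ``hit_fraction`` of the panel plus ``n_extra`` unrelated symbols."""
    rng = _rng(seed, "external")
    out: dict[str, set[str]] = {}
    panel = sorted(panel)
    for k in range(n_sets):
        n_hit = round(hit_fraction * len(panel))
        hits = set(
            panel[i] for i in rng.choice(len(panel), size=n_hit, replace=False)
        ) if panel else set()
        extras = {f"EXT{k}_{i + 1:04d}" for i in range(n_extra)}
        out[f"external_{k + 1}"] = hits | extras
    return out
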
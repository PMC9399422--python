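"""Gene-level collapsing of candidate variants and per-group mutation rates.

Multiple candidate variants in one gene of one sample collapse to a single
binary carrier call; the per-cell provenance keeps the contributing variant
keys.  A gene is declared a "true" mutation in a group when at least 60% of
that group's samples carry a candidate variant, "false" when at most 40% do;
rates strictly between the two bands are reported as indeterminate.  The
threshold comparisons use exact integer arithmetic (k/n vs 3/5 and 2/5) so
boundary rates such as 3/5 never drift under floating point.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import AnnotatedVariant, CohortDesign, VariantKey

#: true/false mutation-rate bands as exact rationals (numerator, denominator)
TRUE_THRESHOLD = (3, 5)  # rate >= 3/5 -> true_mut
FALSE_THRESHOLD = (2, 5)  # rate <= 2/5 -> false_mut


class MutationCall(str, Enum):
    TRUE_MUT = "true_mut"
    FALSE_MUT = "false_mut"
    INDETERMINATE = "indeterminate"


def classify_rate(mutated_count: int, group_size: int) -> MutationCall:
    """Exact-arithmetic true/false/indeterminate call for k carriers of n."""
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if not (0 <= mutated_count <= group_size):
        raise ValueError(f"mutated_count {mutated_count} outside [0, {group_size}]")
    if mutated_count * TRUE_THRESHOLD[1] >= TRUE_THRESHOLD[0] * group_size:
        return MutationCall.TRUE_MUT
    if mutated_count * FALSE_THRESHOLD[1] <= FALSE_THRESHOLD[0] * group_size:
        return MutationCall.FALSE_MUT
    return MutationCall.INDETERMINATE


@dataclass
class GeneMutationMatrix:
    """Binary gene x sample carrier matrix with per-cell variant provenance."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray  # int8, shape (n_genes, n_samples), entries 0/1
    provenance: dict[tuple[str, str], tuple[VariantKey, ...]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("matrix shape does not match gene/sample lists")

    def cell(self, gene: str, sample: str) -> int:
        return int(self.values[self.genes.index(gene), self.samples.index(sample)])

    def restrict_genes(self, genes: Sequence[str]) -> "GeneMutationMatrix":
        keep = [g for g in self.genes if g in set(genes)]
        rows = [self.genes.index(g) for g in keep]
        prov = {
            (g, s): v for (g, s), v in self.provenance.items() if g in set(keep)
        }
        return GeneMutationMatrix(keep, list(self.samples), self.values[rows], prov)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t")

    def write_provenance_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tsample_id\tvariant_key\n")
            for gene in self.genes:
                for sample in self.samples:
                    for key in self.provenance.get((gene, sample), ()):
                        fh.write(f"{gene}\t{sample}\t{key}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GeneMutationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        genes = [str(g) for g in df.index]
        samples = [str(s) for s in df.columns]
        return cls(genes, samples, df.to_numpy(dtype=np.int8), {})


def collapse(
    candidates: Sequence[AnnotatedVariant], design: CohortDesign
) -> GeneMutationMatrix:
    """Collapse candidate variants to a binary gene x sample matrix.

    A cell is 1 iff the sample carries >= 1 candidate variant in the gene;
    genes with no carriers anywhere are pruned.  Genes are sorted
    lexicographically; samples follow design order.
    """
    known = set(design.samples)
    unknown = sorted({v.sample_id for v in candidates} - known)
    if unknown:
        raise ValueError(f"candidate sample(s) not in design: {unknown}")
    prov: dict[tuple[str, str], list[VariantKey]] = {}
    for v in candidates:
        prov.setdefault((v.gene, v.sample_id), []).append(v.key)
    genes = sorted({g for g, _ in prov})
    samples = list(design.samples)
    values = np.zeros((len(genes), len(samples)), dtype=np.int8)
    gidx = {g: i for i, g in enumerate(genes)}
    sidx = {s: j for j, s in enumerate(samples)}
    for (g, s), keys in prov.items():
        values[gidx[g], sidx[s]] = 1
    return GeneMutationMatrix(
        genes, samples, values, {k: tuple(v) for k, v in prov.items()}
    )


@dataclass(frozen=True)
class GroupRate:
    gene: str
    group: str
    mutated_count: int
    group_size: int

    @property
    def rate(self) -> float:
        return self.mutated_count / self.group_size

    @property
    def call(self) -> MutationCall:
        return classify_rate(self.mutated_count, self.group_size)


@dataclass
class GroupMutationRates:
    """Per-(gene, group) carrier counts, rates and true/false calls."""

    design: CohortDesign
    rates: dict[tuple[str, str], GroupRate]  # keyed by (gene, group)

    @property
    def genes(self) -> list[str]:
        return sorted({g for g, _ in self.rates})

    @property
    def groups(self) -> list[str]:
        return self.design.labels

    def get(self, gene: str, group: str) -> GroupRate:
        return self.rates[(gene, group)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": r.gene,
                "group": r.group,
                "mutated_count": r.mutated_count,
                "group_size": r.group_size,
                "rate": r.rate,
                "call": r.call.value,
            }
            for r in self.rates.values()
        ]
        return (
            pd.DataFrame(rows)
            .sort_values(["gene", "group"], kind="stable")
            .reset_index(drop=True)
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, design: CohortDesign) -> "GroupMutationRates":
        rates = {
            (str(r.gene), str(r.group)): GroupRate(
                str(r.gene), str(r.group), int(r.mutated_count), int(r.group_size)
            )
            for r in df.itertuples()
        }
        return cls(design, rates)

    @classmethod
    def read_tsv(cls, path: str | Path, design: CohortDesign) -> "GroupMutationRates":
        return cls.from_frame(pd.read_csv(path, sep="\t"), design)


def group_rates(m: GeneMutationMatrix, design: CohortDesign) -> GroupMutationRates:
    """Per-group carrier counts and true/false calls for every matrix gene."""
    missing = [s for s in design.samples if s not in m.samples]
    if missing:
        raise ValueError(f"design sample(s) missing from matrix: {missing}")
    cols = {s: m.samples.index(s) for s in design.samples}
    rates: dict[tuple[str, str], GroupRate] = {}
    for i, gene in enumerate(m.genes):
        row = m.values[i]
        for label, samples in design.groups:
            k = int(sum(row[cols[s]] for s in samples))
            rates[(gene, label)] = GroupRate(gene, label, k, len(samples))
    return GroupMutationRates(design, rates)


def shared_true_genes(r: GroupMutationRates) -> set[str]:
    """Genes called true_mut in every group (shared putative disease genes)."""
    if len(r.groups) < 2:
        raise ValueError("shared_true_genes needs rates for >= 2 groups")
    return {
        g
        for g in r.genes
        if all(r.get(g, grp).call is MutationCall.TRUE_MUT for grp in r.groups)
    }
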
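"""Differentially mutated gene (DMG) calling, classification, sample
clustering, and the DMG Pearson correlation network.

A gene is a DMG for a pair of groups when the absolute difference of its
per-group carrier rates is at least ``diff_min`` (default 0.6, inclusive).
DMGs enriched in a retinopathy ("case") group are labelled susceptible;
DMGs enriched in the retinopathy-free control group are protective.
Correlation edges connect DMG pairs whose binary carrier profiles across
the pooled cohort correlate with |r| >= 0.8 at p < 0.05 (two-sided t test,
n - 2 degrees of freedom); the |r| threshold captures negative edges too.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from enum import Enum
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list

from .burden_matrix import GeneMutationMatrix, GroupMutationRates

logger = logging.getLogger(__name__)


class DMGLabel(str, Enum):
    SUSCEPTIBLE = "susceptible"
    PROTECTIVE = "protective"
    UNLABELED = "unlabeled"


@dataclass(frozen=True)
class DMGRecord:
    """One gene's pairwise group comparison exceeding the rate-difference cut."""

    gene: str
    group_a: str
    group_b: str
    rate_a: float
    rate_b: float
    abs_diff: float
    enriched_in: str
    label: DMGLabel = DMGLabel.UNLABELED


def _as_fraction(x: float) -> Fraction:
    # thresholds arrive as decimals like 0.6; recover the intended rational
    return Fraction(x).limit_denominator(10**6)


def call_dmgs(
    r: GroupMutationRates,
    comparisons: Sequence[tuple[str, str]],
    diff_min: float = 0.6,
) -> list[DMGRecord]:
    """Call DMGs for each (group_a, group_b) comparison.

    Rate differences are compared to ``diff_min`` in exact rational
    arithmetic, so a difference of exactly 3/5 passes a 0.6 cut.  Output is
    sorted by (gene, group_a, group_b).
    """
    cut = _as_fraction(diff_min)
    known = set(r.groups)
    for a, b in comparisons:
        for g in (a, b):
            if g not in known:
                raise KeyError(f"unknown group label {g!r}")
    records: list[DMGRecord] = []
    for gene in r.genes:
        for a, b in comparisons:
            ra, rb = r.get(gene, a), r.get(gene, b)
            diff = abs(
                Fraction(ra.mutated_count, ra.group_size)
                - Fraction(rb.mutated_count, rb.group_size)
            )
            if diff >= cut:
                enriched = a if ra.rate >= rb.rate else b
                records.append(
                    DMGRecord(
                        gene=gene,
                        group_a=a,
                        group_b=b,
                        rate_a=ra.rate,
                        rate_b=rb.rate,
                        abs_diff=float(diff),
                        enriched_in=enriched,
                    )
                )
    records.sort(key=lambda rec: (rec.gene, rec.group_a, rec.group_b))
    return records


def label_dmgs(
    records: Sequence[DMGRecord],
    case_groups: set[str],
    control_group: str,
) -> list[DMGRecord]:
    """Classify DMGs: enriched in a case group -> susceptible; enriched in
    the control group -> protective; anything else stays unlabeled."""
    out = []
    for rec in records:
        if rec.enriched_in in case_groups:
            label = DMGLabel.SUSCEPTIBLE
        elif rec.enriched_in == control_group:
            label = DMGLabel.PROTECTIVE
        else:
            label = DMGLabel.UNLABELED
        out.append(replace(rec, label=label))
    return out


def dmg_frame(records: Sequence[DMGRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "group_a": r.group_a,
                "group_b": r.group_b,
                "rate_a": r.rate_a,
                "rate_b": r.rate_b,
                "abs_diff": r.abs_diff,
                "enriched_in": r.enriched_in,
                "label": r.label.value,
            }
            for r in records
        ],
        columns=[
            "gene", "group_a", "group_b", "rate_a", "rate_b",
            "abs_diff", "enriched_in", "label",
        ],
    )


def write_dmgs(records: Sequence[DMGRecord], path: str | Path) -> None:
    dmg_frame(records).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pearson correlation network
# ---------------------------------------------------------------------------

class EdgeSign(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class CorrelationEdge:
    gene_i: str
    gene_j: str
    r: float
    p: float

    @property
    def sign(self) -> EdgeSign:
        return EdgeSign.POSITIVE if self.r > 0 else EdgeSign.NEGATIVE


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson r via t = r*sqrt((n-2)/(1-r^2)), df = n-2.

    |r| = 1 returns 0 by convention.
    """
    if n < 3:
        raise ValueError("need >= 3 observations")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def correlation_matrix(m: GeneMutationMatrix) -> pd.DataFrame:
    """Pairwise Pearson r between gene carrier profiles across all samples.

    Zero-variance genes yield NaN rows/columns (no edges); the diagonal
    is 1 for genes with variance.
    """
    x = m.values.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.atleast_2d(r)
    return pd.DataFrame(r, index=m.genes, columns=m.genes)


def pearson_network(
    m: GeneMutationMatrix,
    r_min: float = 0.8,
    p_max: float = 0.05,
    bh_correct: bool = False,
) -> list[CorrelationEdge]:
    """Build the DMG correlation network over the pooled cohort.

    One edge per unordered gene pair with |r| >= r_min and p < p_max
    (raw p by default; Benjamini-Hochberg optional).  Genes whose carrier
    profile has zero variance are logged and yield no edges.
    """
    n = len(m.samples)
    if n < 3:
        raise ValueError("pearson_network needs >= 3 samples")
    x = m.values.astype(float)
    variable = [i for i in range(len(m.genes)) if x[i].std() > 0]
    dropped = [m.genes[i] for i in range(len(m.genes)) if i not in set(variable)]
    if dropped:
        logger.info("zero-variance genes excluded from network: %s", dropped)
    pairs: list[tuple[int, int, float, float]] = []
    for ai, i in enumerate(variable):
        for j in variable[ai + 1 :]:
            xi, xj = x[i], x[j]
            ci, cj = xi - xi.mean(), xj - xj.mean()
            r = float(np.dot(ci, cj) / np.sqrt(np.dot(ci, ci) * np.dot(cj, cj)))
            r = max(-1.0, min(1.0, r))
            pairs.append((i, j, r, pearson_pvalue(r, n)))
    if not pairs:
        return []
    p = np.array([t[3] for t in pairs])
    if bh_correct:
        p = _bh_adjust(p)
    edges = [
        CorrelationEdge(m.genes[i], m.genes[j], r, float(pv))
        for (i, j, r, _), pv in zip(pairs, p)
        if abs(r) >= r_min and pv < p_max
    ]
    return edges


def edge_frame(edges: Sequence[CorrelationEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene_i": e.gene_i, "gene_j": e.gene_j, "r": e.r, "p": e.p,
             "sign": e.sign.value}
            for e in edges
        ],
        columns=["gene_i", "gene_j", "r", "p", "sign"],
    )


def write_edges(edges: Sequence[CorrelationEdge], path: str | Path) -> None:
    edge_frame(edges).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Hierarchical clustering of samples / genes
# ---------------------------------------------------------------------------

def jaccard_distance_matrix(profiles: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard distances between binary row profiles.

    Two all-zero profiles have distance 0 (nothing distinguishes them).
    """
    x = np.asarray(profiles, dtype=bool)
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = np.logical_or(x[i], x[j]).sum()
            if union == 0:
                dij = 0.0
            else:
                inter = np.logical_and(x[i], x[j]).sum()
                dij = 1.0 - inter / union
            d[i, j] = d[j, i] = dij
    return d


def average_linkage(dist: np.ndarray) -> np.ndarray:
    """Agglomerative average linkage (UPGMA) with a deterministic tie-break.

    Cluster distance is the mean of all pairwise leaf distances between the
    two clusters.  Ties in merge distance are broken by the smallest pair of
    cluster indices (original leaves 0..n-1, then n, n+1, ... in merge
    order), so the output is fully determined by the input.  Returns a
    linkage matrix in the standard (n-1) x 4 format.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if n == 0:
        raise ValueError("empty distance matrix")
    if n == 1:
        return np.empty((0, 4))
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    active = sorted(members)
    z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best: tuple[float, int, int] | None = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                # fsum: exactly rounded, so the mean (and hence tie-breaking)
                # does not depend on accumulation order
                d = math.fsum(
                    dist[a, b] for a in members[i] for b in members[j]
                ) / (len(members[i]) * len(members[j]))
                if best is None or (d, i, j) < best:
                    best = (d, i, j)
        d, i, j = best  # type: ignore[misc]
        members[next_id] = members.pop(i) + members.pop(j)
        active = sorted(set(active) - {i, j} | {next_id})
        z[step] = (i, j, d, len(members[next_id]))
        next_id += 1
    return z


@dataclass
class ClusteringResult:
    sample_linkage: np.ndarray
    gene_linkage: np.ndarray
    sample_order: list[str]
    gene_order: list[str]


def cluster_samples(m: GeneMutationMatrix) -> ClusteringResult:
    """Hierarchically cluster samples and genes on binary carrier profiles
    (Jaccard distance, average linkage).  Deterministic for a fixed matrix;
    a single sample or gene yields a trivial one-leaf tree."""
    if len(m.genes) == 0 or len(m.samples) == 0:
        raise ValueError("empty mutation matrix")
    zs = average_linkage(jaccard_distance_matrix(m.values.T))
    zg = average_linkage(jaccard_distance_matrix(m.values))
    s_order = (
        [m.samples[i] for i in leaves_list(zs)] if len(zs) else list(m.samples)
    )
    g_order = [m.genes[i] for i in leaves_list(zg)] if len(zg) else list(m.genes)
    return ClusteringResult(zs, zg, s_order, g_order)
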
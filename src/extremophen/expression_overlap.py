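"""Differentially expressed gene (DEG) selection and set intersection.

DEG thresholds are applied exactly as conventional in the field: p < 0.05
(strict) and ratio-scale fold change > 2 (up) or < 0.5 (down), both strict.
Externally computed (fold change, p) tables are first-class input; a simple
CPM/t-test two-group statistic is shipped only so fully synthetic runs are
self-contained — it is a documented stand-in, not a negative-binomial
differential-expression model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import CohortDesign, ExpressionStat


class Direction(str, Enum):
    UP = "up"
    DOWN = "down"


@dataclass(frozen=True)
class DEGRecord:
    gene: str
    fold_change: float
    p_value: float
    direction: Direction


def select_degs(
    stats_list: Sequence[ExpressionStat],
    p_max: float = 0.05,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
) -> list[DEGRecord]:
    """Select DEGs with strict inequalities: p < p_max and fc > fc_up (up)
    or fc < fc_down (down).  fc == 2.0 or p == 0.05 are excluded.

    Raises on duplicate gene symbols (one statistic per gene required).
    """
    seen: set[str] = set()
    for s in stats_list:
        if s.gene in seen:
            raise ValueError(f"duplicate gene symbol {s.gene!r}")
        seen.add(s.gene)
    out: list[DEGRecord] = []
    for s in stats_list:
        if s.p_value >= p_max:
            continue
        if s.fold_change > fc_up:
            out.append(DEGRecord(s.gene, s.fold_change, s.p_value, Direction.UP))
        elif s.fold_change < fc_down:
            out.append(DEGRecord(s.gene, s.fold_change, s.p_value, Direction.DOWN))
    return out


def deg_frame(records: Sequence[DEGRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene": r.gene, "fold_change": r.fold_change, "p_value": r.p_value,
             "direction": r.direction.value}
            for r in records
        ],
        columns=["gene", "fold_change", "p_value", "direction"],
    )


def write_degs(records: Sequence[DEGRecord], path: str | Path) -> None:
    deg_frame(records).to_csv(path, sep="\t", index=False)


def basic_two_group_stats(
    counts: pd.DataFrame,
    design: CohortDesign,
    group_a: str,
    group_b: str,
) -> list[ExpressionStat]:
    """Simple two-group expression statistic on a gene x sample count matrix.

    Counts are normalised to counts per million with a pseudocount of 1;
    fold change is the ratio of group means of the normalised values
    (group_a over group_b) and p comes from a two-sided unequal-variance
    t test on log2 normalised values.  This is a lightweight stand-in for a
    dispersion-modelling DE method; real DE output can be supplied instead
    via the (gene, fold_change, p_value) table input.
    """
    sa = list(design.group_samples(group_a))
    sb = list(design.group_samples(group_b))
    for label, ss in ((group_a, sa), (group_b, sb)):
        if len(ss) < 2:
            raise ValueError(f"group {label!r} has < 2 samples")
    missing = [s for s in sa + sb if s not in counts.columns]
    if missing:
        raise ValueError(f"samples missing from count matrix: {missing}")
    x = counts[sa + sb].to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    cpm = (x + 1.0) / (x.sum(axis=0, keepdims=True) + x.shape[0]) * 1e6
    a, b = cpm[:, : len(sa)], cpm[:, len(sa) :]
    fc = a.mean(axis=1) / b.mean(axis=1)
    with np.errstate(invalid="ignore"):
        t, p = stats.ttest_ind(np.log2(a), np.log2(b), axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance-in-both-groups genes
    return [
        ExpressionStat(str(g), float(f), float(min(pv, 1.0)))
        for g, f, pv in zip(counts.index, fc, p)
    ]


def intersect_deg_sets(
    named_sets: Mapping[str, Sequence[DEGRecord]],
) -> pd.DataFrame:
    """All 2^k - 1 exclusive Venn regions over k named DEG sets, stratified
    by direction.

    A gene up in one set and down in another is never counted as shared:
    regions are computed separately over the up-genes and the down-genes of
    each set.  Region counts within one direction sum to the size of that
    direction's union.
    """
    names = sorted(named_sets)
    rows = []
    for direction in (Direction.UP, Direction.DOWN):
        genes_by_set = {
            n: {r.gene for r in named_sets[n] if r.direction is direction}
            for n in names
        }
        for k in range(1, len(names) + 1):
            for combo in itertools.combinations(names, k):
                inside = set.intersection(*(genes_by_set[n] for n in combo))
                outside = set().union(
                    *(genes_by_set[n] for n in names if n not in combo)
                ) if len(combo) < len(names) else set()
                region = sorted(inside - outside)
                rows.append(
                    {
                        "direction": direction.value,
                        "sets": "&".join(combo),
                        "degree": k,
                        "n_genes": len(region),
                        "genes": ",".join(region),
                    }
                )
    return pd.DataFrame(
        rows, columns=["direction", "sets", "degree", "n_genes", "genes"]
    )


def shared_degs(
    named_sets: Mapping[str, Sequence[DEGRecord]], direction: Direction
) -> set[str]:
    """Genes carrying the given direction in every named set."""
    sets = [
        {r.gene for r in records if r.direction is direction}
        for records in named_sets.values()
    ]
    return set.intersection(*sets) if sets else set()
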
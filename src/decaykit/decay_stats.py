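"""Comparative statistics over half-life tables.

Conditions are compared gene-by-gene (paired): the per-gene half-life
differences between two conditions go into a two-sided Wilcoxon signed-rank
test, exact for small samples and normal-approximated (with continuity
correction) above.  Genes can be binned by their half-life in a reference
condition — the 3/6/9/12-hour bins distinguish short-lived from long-lived
transcripts — and annotated subsets (IEGs, YTHDF2/TTP/Roquin targets) can be
tested as subgroups.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .halflife_rnaseq import HalfLifeTable

__all__ = [
    "GeneSet",
    "ComparisonResult",
    "BinComparison",
    "compare_paired",
    "bin_halflives",
    "subgroup_analysis",
    "median_halflife",
    "DEFAULT_BIN_EDGES",
]

DEFAULT_BIN_EDGES = (0.0, 3.0, 6.0, 9.0, 12.0, math.inf)

# exact signed-rank null is enumerable up to here; normal approximation above
EXACT_N_MAX = 25


@dataclass(frozen=True)
class GeneSet:
    """A named, duplicate-free gene list."""

    name: str
    genes: tuple

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate IDs")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class ComparisonResult:
    """Paired comparison of half-lives between two conditions.

    ``direction`` describes condition_b relative to condition_a:
    "stabilized" (longer half-lives in b), "destabilized", or "none".
    """

    condition_a: str
    condition_b: str
    n: int
    median_a: float
    median_b: float
    statistic: float
    p_value: float
    direction: str
    method: str = "signed_rank"


def _halflife_frame(table) -> pd.DataFrame:
    if isinstance(table, HalfLifeTable):
        return table.halflives
    return pd.DataFrame(table)


def compare_paired(table, condition_a: str, condition_b: str,
                   method: str = "signed_rank") -> ComparisonResult:
    """Two-sided paired test on per-gene half-lives of two conditions.

    Only genes quantified in both conditions enter.  Zero differences are
    dropped before ranking (Wilcoxon's original treatment); the null is
    exact for n <= 25 usable pairs, normal with continuity correction above.
    ``method='mannwhitney'`` runs an unpaired Mann-Whitney U instead, for
    sensitivity analysis.
    """
    df = _halflife_frame(table)[[condition_a, condition_b]].dropna()
    if len(df) < 6:
        raise ValueError(
            f"only {len(df)} genes shared between conditions; need >= 6"
        )
    a = df[condition_a].to_numpy(dtype=float)
    b = df[condition_b].to_numpy(dtype=float)

    if method == "mannwhitney":
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        stat, p = float(stat), float(p)
    elif method == "signed_rank":
        d = b - a
        d = d[d != 0.0]
        if d.size == 0:
            stat, p = math.nan, 1.0
        else:
            mode = "exact" if d.size <= EXACT_N_MAX else "approx"
            res = stats.wilcoxon(d, zero_method="wilcox", correction=(mode == "approx"),
                                 alternative="two-sided", method=mode)
            stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")

    med_a, med_b = float(np.median(a)), float(np.median(b))
    shift = float(np.median(b - a))
    direction = "stabilized" if shift > 0 else "destabilized" if shift < 0 else "none"
    return ComparisonResult(
        condition_a=condition_a, condition_b=condition_b, n=int(len(df)),
        median_a=med_a, median_b=med_b, statistic=stat, p_value=p,
        direction=direction, method=method,
    )


@dataclass(frozen=True)
class BinComparison:
    """One half-life bin: the (lo, hi] interval on the reference condition,
    its genes, and the paired comparison within it (None when too few)."""

    lo: float
    hi: float
    genes: tuple
    result: ComparisonResult | None

    @property
    def label(self) -> str:
        hi = "∞" if math.isinf(self.hi) else f"{self.hi:g}"
        return f"({self.lo:g}, {hi}] h"


def bin_halflives(table, condition_ref: str, condition_alt: str,
                  edges=DEFAULT_BIN_EDGES, min_genes: int = 6):
    """Bin genes by reference-condition half-life and test each bin.

    Bins are half-open intervals (lo, hi] over ``edges`` (which must be
    increasing); a gene with half-life exactly on an edge falls in the lower
    bin.  Returns a list of :class:`BinComparison`; bins with fewer than
    ``min_genes`` genes carry ``result=None``.
    """
    edges = [float(e) for e in edges]
    if not all(x < y for x, y in zip(edges, edges[1:])):
        raise ValueError("bin edges must be increasing")
    df = _halflife_frame(table)
    out = []
    ref = df[condition_ref]
    for lo, hi in zip(edges, edges[1:]):
        in_bin = (ref > lo) & (ref <= hi)
        genes = tuple(df.index[in_bin])
        if len(genes) >= max(min_genes, 6):  # compare_paired needs >= 6 pairs
            result = compare_paired(df.loc[list(genes)], condition_ref, condition_alt)
        else:
            result = None
        out.append(BinComparison(lo=lo, hi=hi, genes=genes, result=result))
    return out


def subgroup_analysis(table, genesets, condition_a: str, condition_b: str,
                      min_genes: int = 6) -> dict:
    """Paired comparison restricted to each gene set.

    Returns ``{set name: ComparisonResult}``; sets with fewer than
    ``min_genes`` quantified genes are skipped with a warning.
    """
    df = _halflife_frame(table)
    results = {}
    for gs in genesets:
        hit = df.index.intersection(list(gs.genes))
        if len(hit) < min_genes:
            warnings.warn(
                f"gene set {gs.name!r}: only {len(hit)} quantified genes; skipped",
                stacklevel=2,
            )
            continue
        results[gs.name] = compare_paired(df.loc[hit], condition_a, condition_b)
    return results


def median_halflife(table, condition: str) -> float:
    """Sample median half-life (hours) of one condition (midpoint for even n)."""
    values = _halflife_frame(table)[condition].dropna().to_numpy(dtype=float)
    if values.size == 0:
        raise ValueError("no half-lives for condition " + repr(condition))
    return float(np.median(values))


def adjust_pvalues(results: dict, method: str = "bh") -> dict:
    """Benjamini-Hochberg adjustment across a dict of ComparisonResults.

    Off by default everywhere in the package (raw p values are reported);
    provided for users comparing many bins or subgroups.
    """
    if method != "bh":
        raise ValueError("only 'bh' is supported")
    names = list(results)
    raw = [results[n].p_value for n in names]
    adjusted = stats.false_discovery_control(raw, method="bh")
    return dict(zip(names, adjusted))
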
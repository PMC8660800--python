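"""Transcriptome-wide mRNA half-life estimation from actinomycin-D chase RNA-seq.

After transcription shut-off, the abundance of each mRNA decays (to first
order) as A(t) = A0 * exp(-k t).  Because global mRNA levels fall during the
chase while the amount of ERCC spike-in RNA per sample is constant, raw
library-size normalization would mask the decay; instead each sample's gene
counts are divided by that sample's total spike-in count.  A per-gene linear
regression of log normalized counts on time then gives the decay rate
k = -slope and the half-life t1/2 = ln 2 / k.  Genes are only retained when
the fit is reliable (negative slope, R^2 above threshold) in every condition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._regression import LN2, halflife_from_slope, ols

__all__ = [
    "ChaseCountMatrix",
    "DecayFit",
    "HalfLifeTable",
    "normalize_to_spikeins",
    "fit_decay",
    "filter_reliable",
    "run_halflife_pipeline",
]

REQUIRED_SAMPLE_COLUMNS = ("condition", "replicate", "time_h")


@dataclass
class ChaseCountMatrix:
    """Gene x sample integer counts from an actD chase, plus sample metadata.

    Parameters
    ----------
    counts
        Integer counts, genes as rows (index = gene IDs), samples as columns.
    samples
        Sample sheet indexed by sample ID with columns ``condition``,
        ``replicate`` and ``time_h``.
    spikein_ids
        Gene IDs (subset of the count index) that are spike-in features.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    spikein_ids: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.spikein_ids = frozenset(self.spikein_ids)
        missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if not set(self.counts.columns) == set(self.samples.index):
            raise ValueError("count matrix columns and sample sheet rows disagree")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")
        unknown = self.spikein_ids - set(self.counts.index)
        if unknown:
            raise ValueError(f"spike-in IDs absent from count matrix: {sorted(unknown)[:5]}")

    @property
    def conditions(self) -> list:
        return list(dict.fromkeys(self.samples["condition"]))

    @property
    def gene_ids(self) -> pd.Index:
        """Non-spike-in gene IDs."""
        return self.counts.index[~self.counts.index.isin(self.spikein_ids)]

    def spikein_sums(self) -> pd.Series:
        spike = self.counts.loc[self.counts.index.isin(self.spikein_ids)]
        return spike.sum(axis=0)


@dataclass(frozen=True)
class DecayFit:
    """Per-gene, per-condition log-linear decay fit.

    ``slope`` is per hour; ``halflife_h = ln 2 / -slope`` when the slope is
    negative, +inf otherwise.  ``ok`` is False when fewer than three positive
    observations survived (``reason`` says why), in which case the numeric
    fields are NaN.
    """

    gene: str
    condition: str
    slope: float
    intercept: float
    r_squared: float
    halflife_h: float
    n_points: int
    n_dropped: int = 0
    ok: bool = True
    reason: str = ""


def normalize_to_spikeins(matrix: ChaseCountMatrix, scale="median") -> pd.DataFrame:
    """Divide each sample's counts by that sample's total spike-in count.

    ``scale`` rescales the resulting ratios for readability: ``"median"``
    multiplies by the median spike-in sum across samples (so values stay on
    a counts-like scale), a number multiplies by that number, ``1`` leaves
    the raw ratios.  Slopes, R^2 and half-lives downstream are invariant to
    this choice.  Spike-in rows are retained (callers flag them via
    ``matrix.spikein_ids``).
    """
    sums = matrix.spikein_sums()
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(
            f"sample(s) with zero spike-in reads, cannot normalize: {list(zero.index)}"
        )
    normalized = matrix.counts / sums
    if scale == "median":
        factor = float(sums.median())
    else:
        factor = float(scale)
    if factor != 1.0:
        normalized = normalized * factor
    return normalized


def fit_decay(times_h, values, gene: str = "", condition: str = "") -> DecayFit:
    """OLS of ln(value) on time for one gene in one condition.

    Observations with value <= 0 (or NaN) are dropped — the log is undefined
    and a pseudocount would bias fast decayers — and at least three positive
    points at two distinct times must survive, otherwise the fit is marked
    failed rather than raising.
    """
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(values, dtype=float)
    keep = np.isfinite(v) & (v > 0)
    n_dropped = int((~keep).sum())
    t, v = t[keep], v[keep]

    def _failed(reason: str) -> DecayFit:
        return DecayFit(gene, condition, math.nan, math.nan, math.nan, math.nan,
                        n_points=int(t.size), n_dropped=n_dropped, ok=False,
                        reason=reason)

    if t.size < 3:
        return _failed("fewer than 3 positive observations")
    if np.unique(t).size < 2:
        return _failed("fewer than 2 distinct timepoints")
    fit = ols(t, np.log(v))
    return DecayFit(
        gene=gene,
        condition=condition,
        slope=fit.slope,
        intercept=fit.intercept,
        r_squared=fit.r_squared,
        halflife_h=halflife_from_slope(fit.slope),
        n_points=fit.n,
        n_dropped=n_dropped,
    )


@dataclass
class HalfLifeTable:
    """Half-lives (hours) for genes passing the reliability filter in all conditions.

    ``halflives`` is gene x condition; ``status`` records, for every input
    gene, whether it was retained or the first filter rule it failed.
    """

    halflives: pd.DataFrame
    status: pd.Series
    fits: pd.DataFrame | None = None

    @property
    def conditions(self) -> list:
        return list(self.halflives.columns)

    def __len__(self) -> int:
        return len(self.halflives)


def _fits_frame(fits) -> pd.DataFrame:
    if isinstance(fits, pd.DataFrame):
        return fits
    return pd.DataFrame([f.__dict__ for f in fits])


def filter_reliable(fits, r2_min: float = 0.5, spikein_ids=()) -> HalfLifeTable:
    """Keep genes with a positive finite half-life and R^2 strictly above
    ``r2_min`` in every condition; spike-ins are always excluded.

    ``fits`` is an iterable of :class:`DecayFit` (or an equivalent tidy
    DataFrame) covering the same gene universe in each condition.
    """
    df = _fits_frame(fits)
    spikes = set(spikein_ids)
    universes = df.groupby("condition")["gene"].apply(set)
    if len(universes) == 0:
        raise ValueError("no fits supplied")
    first = universes.iloc[0]
    for cond, genes in universes.items():
        if genes != first:
            raise ValueError(f"gene universe of condition {cond!r} differs")

    by_gene = df.groupby("gene", sort=False)
    ok_all = by_gene["ok"].all()
    neg_all = (df["slope"] < 0).groupby(df["gene"], sort=False).all()
    # strict inequality, per the R^2 > 0.5 rule
    rel_all = (df["r_squared"] > r2_min).groupby(df["gene"], sort=False).all()

    genes = df["gene"].drop_duplicates()
    is_spike = genes.isin(spikes).to_numpy()
    status_vals = np.select(
        [
            is_spike,
            ~ok_all.loc[genes].to_numpy(),
            ~neg_all.loc[genes].to_numpy(),
            ~rel_all.loc[genes].to_numpy(),
        ],
        ["spikein", "fit_failed", "nonpositive_decay", "low_r2"],
        default="retained",
    )
    status = pd.Series(status_vals, index=genes.to_numpy(), name="status")
    retained = list(status.index[status == "retained"])

    wide = df.pivot(index="gene", columns="condition", values="halflife_h")
    wide = wide.loc[retained]
    wide.columns.name = None
    return HalfLifeTable(halflives=wide, status=status, fits=df)


def run_halflife_pipeline(
    matrix: ChaseCountMatrix,
    r2_min: float = 0.5,
    pooling: str = "joint",
):
    """Normalize -> per-gene, per-condition decay fit -> reliability filter.

    ``pooling='joint'`` (default) pools all replicate observations of a
    condition into one regression; ``'per_replicate'`` fits each replicate
    separately and averages the resulting half-lives (the filter then applies
    to the pooled R^2 of a joint refit, so the reliability rule is unchanged).

    Fits are performed on the raw count / spike-in-sum ratios, which makes
    every reported slope and half-life exactly invariant to per-sample
    rescaling of the counts.

    Returns ``(table, summary)`` where ``summary`` holds the median half-life
    per condition, the retained-gene count, and exclusion tallies.
    """
    if matrix.counts.empty:
        raise ValueError("empty count matrix")
    if pooling not in ("joint", "per_replicate"):
        raise ValueError(f"unknown pooling mode {pooling!r}")
    for cond in matrix.conditions:
        times = matrix.samples.loc[matrix.samples["condition"] == cond, "time_h"]
        if times.nunique() < 3:
            raise ValueError(f"condition {cond!r} has fewer than 3 distinct timepoints")

    normalized = normalize_to_spikeins(matrix, scale=1)

    all_zero = matrix.counts.loc[matrix.gene_ids].sum(axis=1) == 0
    not_quantified = list(all_zero.index[all_zero])

    fits: list[DecayFit] = []
    per_rep_halflives: dict = {}
    for cond in matrix.conditions:
        cond_samples = matrix.samples.index[matrix.samples["condition"] == cond]
        times = matrix.samples.loc[cond_samples, "time_h"].to_numpy(dtype=float)
        block = normalized.loc[matrix.gene_ids, cond_samples].to_numpy(dtype=float)
        for i, gene in enumerate(matrix.gene_ids):
            if all_zero[gene]:
                continue
            values = block[i]
            fits.append(fit_decay(times, values, gene=gene, condition=cond))
            if pooling == "per_replicate":
                reps = matrix.samples.loc[cond_samples, "replicate"]
                hls = []
                for rep in reps.unique():
                    sel = (reps == rep).to_numpy()
                    f = fit_decay(times[sel], values[sel], gene=gene, condition=cond)
                    if f.ok:
                        hls.append(f.halflife_h)
                per_rep_halflives[(gene, cond)] = float(np.mean(hls)) if hls else math.nan

    table = filter_reliable(fits, r2_min=r2_min, spikein_ids=matrix.spikein_ids)
    if pooling == "per_replicate" and len(table):
        table.halflives = table.halflives.copy()
        for cond in table.conditions:
            table.halflives[cond] = [
                per_rep_halflives.get((g, cond), math.nan) for g in table.halflives.index
            ]

    for gene in not_quantified:
        table.status.loc[gene] = "not_quantified"

    summary = {
        "n_genes": int(len(matrix.gene_ids)),
        "n_retained": int(len(table)),
        "median_halflife_h": {
            c: float(table.halflives[c].median()) if len(table) else math.nan
            for c in matrix.conditions
        },
        "exclusions": table.status[table.status != "retained"].value_counts().to_dict(),
    }
    if len(table) == 0:
        warnings.warn("no genes passed the reliability filter", stacklevel=2)
    return table, summary
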
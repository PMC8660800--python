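"""AP-MS bait-vs-control interactome filtering and SILAC regulation testing.

Affinity purification of a tagged bait followed by label-free MS yields, per
protein, one LFQ intensity per run with many missing values.  Candidate
interactors are revealed by presence/absence logic: a protein must be
confidently identified in the bait purifications (at least ``min_present`` of
the replicates) and absent from every control purification to be called an
exclusive hit.  SILAC heavy/light ratios quantify condition-dependent binding
and are tested against no change (ratio 1) with a two-sided one-sample t test
on the log2 ratios.  A small helper normalizes density-gradient western-blot
profiles to a relative distribution across fractions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProteomicsTable",
    "SilacResult",
    "filter_table",
    "enrich",
    "silac_test",
    "normalize_gradient",
]

FLAG_COLUMNS = ("contaminant", "reverse", "site_only")


@dataclass
class ProteomicsTable:
    """Protein x sample log2 LFQ intensities with flags and sample labels.

    ``intensities``: proteins as rows, samples as columns; NaN marks a protein
    not identified in that run.  ``samples``: indexed by sample ID, columns
    ``label`` ("bait" or "control") and ``replicate``.  ``flags``: boolean
    columns ``contaminant``, ``reverse``, ``site_only`` (MaxQuant-style decoy
    and contaminant markers).  ``silac``: optional protein x replicate log2
    heavy/light ratios.
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame
    flags: pd.DataFrame | None = None
    silac: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if "label" not in self.samples.columns:
            raise ValueError("sample sheet needs a 'label' column (bait/control)")
        if set(self.intensities.columns) != set(self.samples.index):
            raise ValueError("intensity columns and sample sheet rows disagree")
        if self.flags is None:
            self.flags = pd.DataFrame(
                False, index=self.intensities.index, columns=list(FLAG_COLUMNS)
            )

    def sample_ids(self, label: str) -> pd.Index:
        return self.samples.index[self.samples["label"] == label]


def filter_table(
    table: ProteomicsTable,
    min_present: int = 3,
    scope: str = "bait",
) -> ProteomicsTable:
    """Drop flagged proteins, then require identification in enough runs.

    Contaminants, reverse-decoy matches and proteins only identified by a
    modification site are removed outright.  A protein is then retained when
    its intensity is non-missing in at least ``min_present`` of the ``scope``
    samples (``"bait"`` by default; ``"all"`` counts bait and control runs).
    """
    if scope == "bait":
        cols = table.sample_ids("bait")
    elif scope == "all":
        cols = table.intensities.columns
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if min_present > len(cols):
        raise ValueError(
            f"min_present={min_present} exceeds the {len(cols)} available samples"
        )
    flagged = table.flags[list(FLAG_COLUMNS)].any(axis=1)
    present = table.intensities[cols].notna().sum(axis=1)
    keep = (~flagged) & (present >= min_present)
    idx = table.intensities.index[keep]
    return ProteomicsTable(
        intensities=table.intensities.loc[idx],
        samples=table.samples,
        flags=table.flags.loc[idx],
        silac=None if table.silac is None else table.silac.reindex(idx).dropna(how="all"),
    )


def enrich(table: ProteomicsTable) -> pd.DataFrame:
    """Per-protein bait/control mean log2 intensities and exclusivity calls.

    A protein is flagged ``exclusive`` when it was identified in at least one
    bait run and in none of the control runs — the criterion that reveals
    candidate interactors of the purified complex.  Missing values stay
    missing; no imputation (fabricating control signal would defeat the
    presence/absence logic).
    """
    bait_cols = table.sample_ids("bait")
    ctrl_cols = table.sample_ids("control")
    bait = table.intensities[bait_cols]
    ctrl = table.intensities[ctrl_cols]
    result = pd.DataFrame(
        {
            "mean_bait_log2": bait.mean(axis=1),
            "mean_control_log2": ctrl.mean(axis=1),
            "n_bait": bait.notna().sum(axis=1),
            "n_control": ctrl.notna().sum(axis=1),
        }
    )
    result["exclusive"] = (result["n_bait"] > 0) & (result["n_control"] == 0)
    return result


@dataclass(frozen=True)
class SilacResult:
    mean_ratio: float       # linear scale (control set to 1)
    mean_log2_ratio: float
    t_statistic: float
    p_value: float
    n: int


def silac_test(log2_ratios) -> SilacResult:
    """Two-sided one-sample t test of replicate log2 SILAC ratios against 0.

    Testing log2 ratios against 0 is the log-scale reading of "control set
    to 1"; the mean ratio is reported back on the linear scale.  With a
    single replicate only the mean is reported (p undefined); identical
    ratios of exactly 1 give p = 1; nonzero but zero-variance ratios return
    a p floored at the smallest positive float, with a warning.
    """
    x = np.asarray(log2_ratios, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 1:
        raise ValueError("no ratios supplied")
    mean_log2 = float(x.mean())
    if x.size == 1:
        return SilacResult(2.0 ** mean_log2, mean_log2, math.nan, math.nan, 1)
    if float(x.std(ddof=1)) == 0.0:
        if mean_log2 == 0.0:
            return SilacResult(1.0, 0.0, 0.0, 1.0, int(x.size))
        warnings.warn(
            "zero variance across replicate ratios; p floored", stacklevel=2
        )
        t = math.inf if mean_log2 > 0 else -math.inf
        return SilacResult(
            2.0 ** mean_log2, mean_log2, t, float(np.finfo(float).tiny), int(x.size)
        )
    t, p = stats.ttest_1samp(x, popmean=0.0)
    return SilacResult(2.0 ** mean_log2, mean_log2, float(t), float(p), int(x.size))


def normalize_gradient(profile) -> pd.DataFrame:
    """Convert per-fraction band intensities to a relative distribution.

    ``profile``: fractions x proteins (DataFrame or 2-D array; a 1-D array is
    a single protein).  Each protein's intensities are divided by its total
    so every column sums to 1.
    """
    df = pd.DataFrame(profile)
    if (np.asarray(df) < 0).any():
        raise ValueError("band intensities must be non-negative")
    totals = df.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"protein(s) with zero total intensity: {bad}")
    return df / totals
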
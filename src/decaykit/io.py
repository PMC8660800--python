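"""Readers and writers for the plain-text formats the package consumes.

Count matrices arrive as featureCounts-style TSV (either the full 7-column
dialect with Geneid/Chr/Start/End/Strand/Length annotation columns, or a
bare gene x sample matrix); sample sheets, lane profiles, marker tables and
abundance series as CSV; gene sets as GMT; AP-MS tables as MaxQuant
proteinGroups-style TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .decay_stats import GeneSet
from .halflife_rnaseq import ChaseCountMatrix, HalfLifeTable
from .interactome import FLAG_COLUMNS, ProteomicsTable
from .synthetic import LaneProfile

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_spikein_ids",
    "write_spikein_ids",
    "read_chase",
    "read_gmt",
    "write_gmt",
    "read_lane_profiles",
    "write_lane_profiles",
    "read_marker_table",
    "read_abundance_series",
    "write_halflife_table",
    "write_run_summary",
    "read_protein_groups",
]

FEATURECOUNTS_ANNOTATION = ("Chr", "Start", "End", "Strand", "Length")


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a featureCounts-style TSV into a gene x sample integer frame.

    Comment lines starting with '#' are skipped.  If the header carries the
    featureCounts annotation columns (Chr/Start/End/Strand/Length) they are
    dropped; otherwise the file is treated as a bare matrix whose first
    column is the gene ID.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.set_index(df.columns[0])
    drop = [c for c in FEATURECOUNTS_ANNOTATION if c in df.columns]
    if drop:
        df = df.drop(columns=drop)
    return df.astype(np.int64)


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="Geneid")


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet CSV with columns sample, condition, replicate, time_h."""
    df = pd.read_csv(path)
    return df.set_index("sample")


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index_label="sample")


def read_spikein_ids(path) -> frozenset:
    text = Path(path).read_text()
    return frozenset(line.strip() for line in text.splitlines() if line.strip())


def write_spikein_ids(ids, path) -> None:
    Path(path).write_text("\n".join(sorted(ids)) + "\n")


def read_chase(counts_path, samples_path, spikeins_path) -> ChaseCountMatrix:
    """Assemble a ChaseCountMatrix from its three on-disk pieces."""
    return ChaseCountMatrix(
        counts=read_counts_tsv(counts_path),
        samples=read_sample_sheet(samples_path),
        spikein_ids=read_spikein_ids(spikeins_path),
    )


def read_gmt(path) -> list:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets.append(GeneSet(name=fields[0], genes=tuple(fields[2:])))
    return sets


def write_gmt(genesets, path, description: str = "") -> None:
    lines = [
        "\t".join([gs.name, description, *gs.genes]) for gs in genesets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_lane_profiles(path) -> list:
    """Lane-profile CSV with columns lane, position, intensity and optionally
    time_min; returns one LaneProfile per lane, ordered by time."""
    df = pd.read_csv(path)
    profiles = []
    for lane, group in df.groupby("lane", sort=True):
        group = group.sort_values("position")
        time = float(group["time_min"].iloc[0]) if "time_min" in group else float(lane)
        profiles.append(
            LaneProfile(group["position"].to_numpy(),
                        group["intensity"].to_numpy(), time_min=time)
        )
    profiles.sort(key=lambda p: p.time_min)
    return profiles


def write_lane_profiles(profiles, path) -> None:
    frames = []
    for i, lane in enumerate(profiles):
        frames.append(pd.DataFrame({
            "lane": i,
            "position": lane.positions,
            "intensity": lane.intensities,
            "time_min": lane.time_min,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_marker_table(path) -> pd.DataFrame:
    """Marker-band CSV with columns position, tail_nt."""
    df = pd.read_csv(path)
    missing = {"position", "tail_nt"} - set(df.columns)
    if missing:
        raise ValueError(f"marker table missing columns: {sorted(missing)}")
    return df


def read_abundance_series(path) -> pd.DataFrame:
    """Targeted-series CSV: feature, reference, time_h, target, reference_signal."""
    return pd.read_csv(path)


def write_halflife_table(table: HalfLifeTable, path) -> None:
    out = table.halflives.copy()
    if table.fits is not None:
        for cond in table.halflives.columns:
            sub = table.fits[table.fits["condition"] == cond].set_index("gene")
            out[f"r_squared_{cond}"] = sub.loc[out.index, "r_squared"]
            out[f"n_points_{cond}"] = sub.loc[out.index, "n_points"]
    out.to_csv(path, index_label="gene")


def write_run_summary(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, default=float) + "\n")


def read_protein_groups(path, bait_samples, control_samples) -> ProteomicsTable:
    """Read a MaxQuant proteinGroups-style TSV.

    ``bait_samples``/``control_samples`` name the runs, matching the
    "LFQ intensity <run>" columns.  '+' in "Reverse", "Potential contaminant"
    and "Only identified by site" marks flagged rows; LFQ intensities of 0
    are treated as missing and values are log2-transformed.
    """
    df = pd.read_csv(path, sep="\t")
    ids = df[df.columns[df.columns.str.lower().str.startswith("protein ids")][0]]
    runs = list(bait_samples) + list(control_samples)
    lfq = {}
    for run in runs:
        col = f"LFQ intensity {run}"
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
        vals = df[col].astype(float).replace(0.0, np.nan)
        lfq[run] = np.log2(vals)
    intensities = pd.DataFrame(lfq)
    intensities.index = ids

    def _flag(col: str) -> pd.Series:
        if col in df.columns:
            return df[col].fillna("").astype(str).str.strip().eq("+").to_numpy()
        return np.zeros(len(df), dtype=bool)

    flags = pd.DataFrame(
        {
            "contaminant": _flag("Potential contaminant"),
            "reverse": _flag("Reverse"),
            "site_only": _flag("Only identified by site"),
        },
        index=ids,
    )[list(FLAG_COLUMNS)]
    samples = pd.DataFrame(
        {
            "label": ["bait"] * len(bait_samples) + ["control"] * len(control_samples),
            "replicate": list(range(1, len(bait_samples) + 1))
            + list(range(1, len(control_samples) + 1)),
        },
        index=runs,
    )
    return ProteomicsTable(intensities=intensities, samples=samples, flags=flags)
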
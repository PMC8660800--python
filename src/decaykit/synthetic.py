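"""Synthetic inputs with known ground truth for every stage of the package.

Four generators emulate the assays the analysis modules consume:

* :func:`simulate_chase` — an actinomycin-D chase RNA-seq experiment.  Each
  gene decays exponentially from its time-zero abundance at rate
  k = ln 2 / t1/2, optionally accelerated by a condition-wide multiplier
  (a globally destabilized cell line) and by gene-set-specific multipliers
  (e.g. an IEG-like labile subset).  ERCC-style spike-in features keep a
  constant abundance.  Each library is sequenced to a fixed expected depth,
  so reads are allocated in proportion to the (shrinking) molar pool and
  counts are drawn negative-binomially around those expectations.
* :func:`simulate_lane_profiles` — densitometry line scans of a denaturing
  gel deadenylation assay: a Gaussian band whose modal poly(A) tail walks
  down the ladder at a fixed rate (As/min), plus a marker lane.
* :func:`simulate_qpcr_series` — a target/reference qPCR chase series with
  multiplicative log-normal noise.
* :func:`simulate_apms` — bait-vs-control LFQ tables with planted complex
  members (present only in bait runs), Bernoulli missingness, and SILAC
  log2 ratios scattered around per-protein true means.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._regression import LN2
from .halflife_rnaseq import ChaseCountMatrix
from .interactome import FLAG_COLUMNS, ProteomicsTable

__all__ = [
    "GeneSetEffect",
    "ChaseSimConfig",
    "simulate_chase",
    "LaneProfile",
    "GelSim",
    "simulate_lane_profiles",
    "simulate_qpcr_series",
    "simulate_apms",
]


# ---------------------------------------------------------------------------
# actD chase RNA-seq
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSetEffect:
    """Extra decay multiplier for a gene subset, per condition.

    Membership is either an explicit index list or, by default, a
    deterministic consecutive range (``start`` .. ``start + size``) so that
    subgroup analyses are reproducible.  ``multipliers`` maps condition name
    to the extra factor applied on top of the condition's global multiplier;
    conditions not listed get 1.0.
    """

    name: str
    size: int = 0
    start: int = 0
    indices: tuple = ()
    multipliers: dict = field(default_factory=dict)

    def member_indices(self) -> np.ndarray:
        if len(self.indices):
            return np.asarray(self.indices, dtype=int)
        return np.arange(self.start, self.start + self.size, dtype=int)


@dataclass
class ChaseSimConfig:
    """Study design for a simulated actD chase RNA-seq experiment.

    Defaults mirror a transcriptome-wide chase in parental cells versus a
    globally destabilized knockout: true half-lives log-normal with median
    4.9 h, the KO accelerating every gene's decay by 4.9/4.0, four timepoints
    (0/2/4/6 h), two replicates, 5e6 expected reads per library with 5% of
    the time-zero library from 92 constant spike-in species, and negative
    binomial counts with size (dispersion) parameter 50.
    """

    n_genes: int = 2000
    timepoints_h: tuple = (0.0, 2.0, 4.0, 6.0)
    n_replicates: int = 2
    conditions: tuple = (("parental", 1.0), ("KO", 4.9 / 4.0))
    halflife_log_mean: float = math.log(4.9)
    halflife_log_sd: float = 0.5
    library_depth: float = 5e6
    nb_dispersion: float = 50.0   # NB size parameter; inf = Poisson
    spikein_fraction: float = 0.05
    n_spikeins: int = 92
    abundance_log_sd: float = 1.0
    geneset_effects: tuple = ()
    seed: int = 0

    def validate(self) -> None:
        t = np.asarray(self.timepoints_h, dtype=float)
        if t.size < 2 or not (np.diff(t) > 0).all():
            raise ValueError("timepoints must be strictly increasing")
        if t[0] != 0:
            raise ValueError("timepoints must include 0")
        if self.n_genes < 1 or self.n_replicates < 1 or self.n_spikeins < 1:
            raise ValueError("counts must be >= 1")
        if any(m <= 0 for _, m in self.conditions):
            raise ValueError("condition decay multipliers must be > 0")
        if not (0.0 < self.spikein_fraction < 1.0):
            raise ValueError("spikein_fraction must be in (0, 1)")
        if self.library_depth * self.spikein_fraction < 1.0:
            raise ValueError(
                "library depth too small to allot one expected spike-in read"
            )
        for eff in self.geneset_effects:
            idx = eff.member_indices()
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_genes):
                raise ValueError(f"gene set {eff.name!r} indices out of range")
            if any(m <= 0 for m in eff.multipliers.values()):
                raise ValueError(f"gene set {eff.name!r} multipliers must be > 0")


def draw_halflives(config: ChaseSimConfig) -> np.ndarray:
    """True base half-lives (hours) for a config: the first RNG draw of
    :func:`simulate_chase`, exposed so designs can be built around a known
    draw (e.g. effects confined to long-lived genes) and then re-simulated
    with the same seed."""
    rng = np.random.default_rng(config.seed)
    return rng.lognormal(config.halflife_log_mean, config.halflife_log_sd,
                         config.n_genes)


def simulate_chase(config: ChaseSimConfig):
    """Simulate an actD chase experiment; returns ``(matrix, truth)``.

    ``matrix`` is a :class:`~decaykit.halflife_rnaseq.ChaseCountMatrix`;
    ``truth`` is a tidy DataFrame with one row per gene x condition holding
    the true condition-specific half-life, decay rate, time-zero relative
    abundance and gene-set membership.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    halflives = rng.lognormal(config.halflife_log_mean, config.halflife_log_sd,
                              config.n_genes)
    k_base = LN2 / halflives
    abundance = rng.lognormal(0.0, config.abundance_log_sd, config.n_genes)
    # spike-in species span a wide dynamic range, like an ERCC mix
    spike_abund = rng.lognormal(0.0, config.abundance_log_sd, config.n_spikeins)
    # scale the constant spike-in pool so it takes spikein_fraction of the
    # time-zero library
    spike_abund *= (
        config.spikein_fraction / (1.0 - config.spikein_fraction)
        * abundance.sum() / spike_abund.sum()
    )

    gene_ids = [f"GENE{i:05d}" for i in range(config.n_genes)]
    spike_ids = [f"ERCC-{i:05d}" for i in range(config.n_spikeins)]

    set_membership = {}
    extra = {cond: np.ones(config.n_genes) for cond, _ in config.conditions}
    for eff in config.geneset_effects:
        idx = eff.member_indices()
        member = np.zeros(config.n_genes, dtype=bool)
        member[idx] = True
        set_membership[eff.name] = member
        for cond, _ in config.conditions:
            extra[cond][idx] *= eff.multipliers.get(cond, 1.0)

    timepoints = np.asarray(config.timepoints_h, dtype=float)
    dispersion = config.nb_dispersion

    sample_rows = []
    count_cols = {}
    truth_rows = []
    for cond, mult in config.conditions:
        k_cond = k_base * mult * extra[cond]
        halflife_cond = LN2 / k_cond
        truth = pd.DataFrame(
            {
                "gene": gene_ids,
                "condition": cond,
                "true_halflife_h": halflife_cond,
                "true_k_per_h": k_cond,
                "true_abundance_t0": abundance,
            }
        )
        for name, member in set_membership.items():
            truth[f"in_{name}"] = member
        truth_rows.append(truth)

        for rep in range(1, config.n_replicates + 1):
            for t in timepoints:
                sid = f"{cond}_r{rep}_t{t:g}"
                mu_genes = abundance * np.exp(-k_cond * t)
                pool = np.concatenate([mu_genes, spike_abund])
                expected = config.library_depth * pool / pool.sum()
                exp_genes = expected[: config.n_genes]
                exp_spikes = expected[config.n_genes:]
                if math.isinf(dispersion):
                    gene_counts = rng.poisson(exp_genes)
                else:
                    p = dispersion / (dispersion + exp_genes)
                    gene_counts = rng.negative_binomial(dispersion, p)
                # spike-ins are pipetted at fixed mass: no biological
                # replicate variability, only counting (Poisson) noise
                spike_counts = rng.poisson(exp_spikes)
                count_cols[sid] = np.concatenate([gene_counts, spike_counts])
                sample_rows.append(
                    {"sample": sid, "condition": cond, "replicate": rep,
                     "time_h": float(t)}
                )

    counts = pd.DataFrame(count_cols, index=gene_ids + spike_ids, dtype=np.int64)
    samples = pd.DataFrame(sample_rows).set_index("sample")
    matrix = ChaseCountMatrix(counts=counts, samples=samples,
                              spikein_ids=frozenset(spike_ids))
    truth = pd.concat(truth_rows, ignore_index=True)
    return matrix, truth


def rescue_design_config(
    seed: int = 0,
    n_genes: int = 2000,
    ko_multiplier: float = 4.9 / 4.0,
    ringmut_multiplier: float = 1.3,
    longlived_threshold_h: float = 9.0,
    **overrides,
) -> ChaseSimConfig:
    """Four-condition rescue design: parental, global knockout, full wild-type
    rescue, and a RING-mutant rescue whose deficit is confined to long-lived
    mRNAs.

    The knockout accelerates every gene by ``ko_multiplier``; the WT rescue
    restores parental decay exactly; the RING-mutant rescue restores it for
    short-lived genes but leaves genes with base half-life above
    ``longlived_threshold_h`` accelerated by ``ringmut_multiplier``.  The
    long-lived membership is taken from an effect-free half-life draw with
    the same seed (the draw is the generator's first RNG use, so the final
    simulation reproduces it exactly).
    """
    base = ChaseSimConfig(
        n_genes=n_genes,
        conditions=(
            ("parental", 1.0),
            ("KO", ko_multiplier),
            ("WT", 1.0),
            ("RINGmut", 1.0),
        ),
        seed=seed,
        **overrides,
    )
    halflives = draw_halflives(base)
    idx = np.flatnonzero(halflives > longlived_threshold_h)
    effect = GeneSetEffect(
        name="longlived",
        indices=tuple(int(i) for i in idx),
        multipliers={"RINGmut": ringmut_multiplier},
    )
    return replace(base, geneset_effects=(effect,))


# ---------------------------------------------------------------------------
# gel densitometry
# ---------------------------------------------------------------------------

@dataclass
class LaneProfile:
    """One densitometry line scan: strictly increasing migration positions
    with the scanned intensity at each, and the reaction time of the lane."""

    positions: np.ndarray
    intensities: np.ndarray
    time_min: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.intensities.shape:
            raise ValueError("positions and intensities must be equal-length 1-D")
        if not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")


@dataclass
class GelSim:
    """Output of :func:`simulate_lane_profiles`."""

    profiles: list           # one LaneProfile per timepoint
    marker_table: pd.DataFrame   # columns: position, tail_nt (total length)
    marker_profile: LaneProfile  # noiseless marker lane
    truth: pd.DataFrame          # columns: time_min, tail_As
    body_nt: int = 7


def _position_of(nt: np.ndarray, max_nt: float) -> np.ndarray:
    # shorter RNAs migrate farther; locally linear position vs length
    return 10.0 + 4.0 * (max_nt - np.asarray(nt, dtype=float))


def simulate_lane_profiles(
    rate_As_per_min: float,
    timepoints_min,
    tail0: int = 20,
    band_sigma: float = 2.0,
    noise_sd: float = 0.02,
    marker_tails=None,
    body_nt: int = 7,
    seed: int = 0,
) -> GelSim:
    """Simulate line scans of a deadenylation time course.

    The substrate is a ``body_nt``-mer body carrying ``tail0`` adenosines;
    at time t the modal intermediate has ``max(0, round(tail0 - rate * t))``
    As left.  Each lane is a unit-height Gaussian band (sd ``band_sigma``
    position units) at that intermediate's migration position plus additive
    Gaussian noise.  ``marker_tails`` are total lengths (nt) of the marker
    bands, default 27/22/17/12/7 — substrate down to the fully deadenylated
    body.
    """
    if rate_As_per_min < 0:
        raise ValueError("rate must be >= 0")
    if tail0 < 0:
        raise ValueError("tail0 must be >= 0")
    if band_sigma <= 0 or noise_sd < 0:
        raise ValueError("band_sigma must be > 0 and noise_sd >= 0")
    if marker_tails is None:
        marker_tails = (body_nt + tail0, 22, 17, 12, body_nt)
    marker_tails = np.asarray(sorted(set(marker_tails), reverse=True), dtype=float)
    if len(marker_tails) < 2:
        raise ValueError("need at least 2 distinct marker bands")

    rng = np.random.default_rng(seed)
    max_nt = float(marker_tails.max())
    grid = np.arange(0.0, _position_of(body_nt - 2, max_nt), 0.5)

    marker_pos = _position_of(marker_tails, max_nt)
    marker_table = pd.DataFrame({"position": marker_pos, "tail_nt": marker_tails})
    marker_int = np.zeros_like(grid)
    for pos in marker_pos:
        marker_int += np.exp(-0.5 * ((grid - pos) / band_sigma) ** 2)
    marker_profile = LaneProfile(grid, marker_int, time_min=-1.0)

    profiles, truth_rows = [], []
    for t in np.asarray(timepoints_min, dtype=float):
        true_tail = max(0.0, float(np.round(tail0 - rate_As_per_min * t)))
        center = _position_of(body_nt + true_tail, max_nt)
        intensity = np.exp(-0.5 * ((grid - center) / band_sigma) ** 2)
        intensity = intensity + rng.normal(0.0, noise_sd, grid.size)
        profiles.append(LaneProfile(grid, intensity, time_min=float(t)))
        truth_rows.append({"time_min": float(t), "tail_As": true_tail})

    return GelSim(
        profiles=profiles,
        marker_table=marker_table,
        marker_profile=marker_profile,
        truth=pd.DataFrame(truth_rows),
        body_nt=body_nt,
    )


# ---------------------------------------------------------------------------
# qPCR chase
# ---------------------------------------------------------------------------

def simulate_qpcr_series(
    t_half_h: float,
    timepoints_h,
    noise_cv: float = 0.0,
    seed: int = 0,
    feature: str = "target",
    reference: str = "18S",
) -> pd.DataFrame:
    """Target/reference qPCR chase series with multiplicative noise.

    The target decays as 2^(-t / t1/2); the reference (an rRNA, untouched by
    the chase) stays at 1.  Both signals carry independent log-normal noise
    with coefficient of variation ``noise_cv`` and mean 1.
    """
    if t_half_h <= 0:
        raise ValueError("t_half_h must be > 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    t = np.asarray(timepoints_h, dtype=float)
    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        sigma = math.sqrt(math.log1p(noise_cv ** 2))
        noise_t = rng.lognormal(-sigma ** 2 / 2, sigma, t.size)
        noise_r = rng.lognormal(-sigma ** 2 / 2, sigma, t.size)
    else:
        noise_t = noise_r = np.ones(t.size)
    target = np.exp(-LN2 / t_half_h * t) * noise_t
    ref = np.ones(t.size) * noise_r
    return pd.DataFrame(
        {
            "feature": feature,
            "reference": reference,
            "time_h": t,
            "target": target,
            "reference_signal": ref,
        }
    )


# ---------------------------------------------------------------------------
# AP-MS / SILAC
# ---------------------------------------------------------------------------

def simulate_apms(
    n_background: int = 300,
    complex_members=("CNOT1", "CNOT2", "CNOT3", "CNOT7", "CNOT9"),
    bait_enrichment_log2: float = 3.0,
    silac_regulated=None,
    missing_rate: float = 0.1,
    n_replicates: int = 4,
    silac_sd: float = 0.1,
    seed: int = 0,
) -> ProteomicsTable:
    """Bait-vs-control LFQ tables with planted complex members.

    Background proteins appear in both bait and control purifications;
    ``complex_members`` appear only in the bait runs (at the background
    intensity plus ``bait_enrichment_log2``), so presence/absence filtering
    can recover them.  Every protein x sample intensity is independently
    missing with probability ``missing_rate``.  SILAC log2 ratios are drawn
    normal around 0, or around ``silac_regulated[protein]`` for regulated
    proteins, with sd ``silac_sd``.
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    silac_regulated = dict(silac_regulated or {})
    rng = np.random.default_rng(seed)

    background = [f"BG{i:04d}" for i in range(n_background)]
    members = list(complex_members)
    proteins = members + background

    bait_cols = [f"bait_{r}" for r in range(1, n_replicates + 1)]
    ctrl_cols = [f"control_{r}" for r in range(1, n_replicates + 1)]

    base = rng.normal(25.0, 2.0, len(proteins))
    n_samples = 2 * n_replicates
    intensity = np.tile(base[:, None], (1, n_samples)) + rng.normal(
        0.0, 0.3, (len(proteins), n_samples)
    )
    intensity[: len(members), :n_replicates] += bait_enrichment_log2
    intensity[: len(members), n_replicates:] = np.nan  # bait-only proteins
    miss = rng.random((len(proteins), n_samples)) < missing_rate
    intensity[miss] = np.nan

    intensities = pd.DataFrame(intensity, index=proteins,
                               columns=bait_cols + ctrl_cols)
    samples = pd.DataFrame(
        {
            "label": ["bait"] * n_replicates + ["control"] * n_replicates,
            "replicate": list(range(1, n_replicates + 1)) * 2,
        },
        index=bait_cols + ctrl_cols,
    )
    flags = pd.DataFrame(False, index=proteins, columns=list(FLAG_COLUMNS))

    silac_means = np.array([silac_regulated.get(p, 0.0) for p in proteins])
    silac = pd.DataFrame(
        rng.normal(silac_means[:, None], silac_sd, (len(proteins), n_replicates)),
        index=proteins,
        columns=[f"ratio_{r}" for r in range(1, n_replicates + 1)],
    )
    return ProteomicsTable(intensities=intensities, samples=samples,
                           flags=flags, silac=silac)
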
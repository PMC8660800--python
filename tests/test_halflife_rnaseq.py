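"""Spike-in normalization, per-gene decay fits and the reliability filter."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from decaykit import (
    ChaseCountMatrix,
    ChaseSimConfig,
    fit_decay,
    filter_reliable,
    normalize_to_spikeins,
    run_halflife_pipeline,
    simulate_chase,
)
from decaykit._regression import LN2
from decaykit.halflife_rnaseq import DecayFit


class TestNormalize:
    def test_spike_sum_ratio(self):
        """Spike sums 1e6 and 2e6 with equal gene counts -> normalized 2:1."""
        samples = pd.DataFrame(
            {"condition": ["c", "c"], "replicate": [1, 1], "time_h": [0.0, 1.0]},
            index=["a", "b"],
        )
        counts = pd.DataFrame(
            {"a": [100, 10**6], "b": [100, 2 * 10**6]},
            index=["g", "ERCC-1"], dtype=np.int64,
        )
        m = ChaseCountMatrix(counts, samples, {"ERCC-1"})
        norm = normalize_to_spikeins(m, scale=1)
        assert norm.loc["g", "a"] == 2 * norm.loc["g", "b"]

    def test_matches_elementwise_division_oracle(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(44)] + [f"ERCC-{i}" for i in range(6)]
        counts = pd.DataFrame(
            rng.integers(0, 5000, (50, 6)),
            index=genes, columns=[f"s{i}" for i in range(6)], dtype=np.int64,
        )
        samples = pd.DataFrame(
            {"condition": "c", "replicate": 1, "time_h": np.arange(6.0)},
            index=counts.columns,
        )
        m = ChaseCountMatrix(counts, samples, {g for g in genes if "ERCC" in g})
        norm = normalize_to_spikeins(m)  # default median scale
        sums = counts.loc[[g for g in genes if "ERCC" in g]].sum(axis=0)
        scale = np.median(sums)
        for s in counts.columns:  # brute-force recompute
            expected = counts[s].to_numpy() / sums[s] * scale
            np.testing.assert_array_equal(norm[s].to_numpy(), expected)

    def test_zero_spike_sum_names_sample(self):
        samples = pd.DataFrame(
            {"condition": ["c"] * 3, "replicate": 1, "time_h": [0.0, 1.0, 2.0]},
            index=["s0", "s1", "s2"],
        )
        counts = pd.DataFrame(
            {"s0": [5, 9], "s1": [5, 0], "s2": [5, 3]},
            index=["g", "ERCC-1"], dtype=np.int64,
        )
        m = ChaseCountMatrix(counts, samples, {"ERCC-1"})
        with pytest.raises(ValueError, match="s1"):
            normalize_to_spikeins(m)


class TestFitDecay:
    def test_exact_twofold_series(self):
        fit = fit_decay([0, 1, 2, 3], [100, 50, 25, 12.5])
        assert fit.slope == pytest.approx(-LN2, abs=1e-12)
        assert fit.halflife_h == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_series_has_infinite_halflife(self):
        fit = fit_decay([0, 1, 2, 3], [7.0, 7.0, 7.0, 7.0])
        assert fit.ok
        assert fit.slope == 0.0
        assert fit.halflife_h == math.inf

    def test_zero_values_dropped_and_counted(self):
        fit = fit_decay([0, 1, 2, 3], [100, 0, 25, 12.5])
        assert fit.ok and fit.n_points == 3 and fit.n_dropped == 1

    def test_too_few_positive_points_marks_failed(self):
        fit = fit_decay([0, 1, 2, 3], [100, 0, 0, 12.5], gene="g")
        assert not fit.ok
        assert "positive" in fit.reason
        assert math.isnan(fit.halflife_h)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_closed_form_ols_oracle(self, seed):
        """Seeded noisy series: slope and R^2 equal the normal equations."""
        rng = np.random.default_rng(seed)
        t = np.repeat([0.0, 2.0, 4.0, 6.0], 2)
        v = 100 * np.exp(-0.2 * t) * rng.lognormal(0, 0.1, t.size)
        fit = fit_decay(t, v)
        y = np.log(v)
        tb, yb = t.mean(), y.mean()
        slope = ((t - tb) @ (y - yb)) / ((t - tb) @ (t - tb))
        resid = y - (yb + slope * (t - tb))
        r2 = 1 - (resid @ resid) / ((y - yb) @ (y - yb))
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.r_squared == pytest.approx(r2, abs=1e-10)


def _fit(gene, cond, slope, r2, ok=True):
    hl = LN2 / -slope if slope < 0 else math.inf
    return DecayFit(gene, cond, slope, 0.0, r2, hl, 4, ok=ok,
                    reason="" if ok else "x")


class TestFilterReliable:
    def test_r2_exactly_at_threshold_is_excluded(self):
        fits = [_fit("g", "a", -0.2, 0.5), _fit("g", "b", -0.2, 0.9)]
        table = filter_reliable(fits, r2_min=0.5)
        assert len(table) == 0
        assert table.status["g"] == "low_r2"

    def test_positive_slope_excluded_despite_high_r2(self):
        fits = [_fit("g", "a", 0.1, 0.99), _fit("g", "b", -0.2, 0.99)]
        table = filter_reliable(fits)
        assert len(table) == 0
        assert table.status["g"] == "nonpositive_decay"

    def test_spikeins_always_excluded(self):
        fits = [_fit("ERCC-1", "a", -0.2, 0.99)]
        table = filter_reliable(fits, spikein_ids={"ERCC-1"})
        assert len(table) == 0
        assert table.status["ERCC-1"] == "spikein"

    def test_disjoint_gene_universes_error(self):
        fits = [_fit("g1", "a", -0.2, 0.9), _fit("g2", "b", -0.2, 0.9)]
        with pytest.raises(ValueError, match="universe"):
            filter_reliable(fits)

    def test_matches_row_scan_oracle(self, small_chase):
        """Retained set equals an independent row scan of the three rules."""
        matrix, _ = small_chase
        table, _ = run_halflife_pipeline(matrix)
        fits = table.fits
        retained_oracle = set()
        for gene in fits["gene"].unique():
            rows = fits[fits["gene"] == gene]
            if (rows["ok"].all() and (rows["slope"] < 0).all()
                    and (rows["r_squared"] > 0.5).all()):
                retained_oracle.add(gene)
        assert set(table.halflives.index) == retained_oracle


class TestPipeline:
    def test_scale_invariance_is_float_exact(self, small_chase):
        """Rescaling one sample's library leaves every half-life bit-identical."""
        matrix, _ = small_chase
        table1, _ = run_halflife_pipeline(matrix)
        scaled = matrix.counts.copy()
        scaled["parental_r1_t2"] *= 10
        m2 = ChaseCountMatrix(scaled, matrix.samples, matrix.spikein_ids)
        table2, _ = run_halflife_pipeline(m2)
        pd.testing.assert_frame_equal(table1.halflives, table2.halflives)
        assert (table1.halflives.to_numpy() == table2.halflives.to_numpy()).all()

    def test_recovery_of_true_halflives(self, small_chase):
        """Well-covered, not-too-stable genes come back within 15%."""
        matrix, truth = small_chase
        table, _ = run_halflife_pipeline(matrix)
        truth_w = truth.pivot(index="gene", columns="condition",
                              values="true_halflife_h")
        mean_counts = matrix.counts.loc[table.halflives.index].mean(axis=1)
        for cond in table.conditions:
            sel = (mean_counts >= 50) & (truth_w.loc[table.halflives.index, cond] <= 12)
            est = table.halflives.loc[sel[sel].index, cond]
            rel_err = np.abs(est - truth_w.loc[est.index, cond]) / truth_w.loc[est.index, cond]
            assert np.median(rel_err) < 0.15

    def test_monotone_in_decay_multiplier(self):
        """Raising the global decay multiplier lowers the recovered median."""
        cfg = ChaseSimConfig(
            n_genes=300, library_depth=2e6, n_spikeins=20,
            nb_dispersion=math.inf,
            conditions=(("m10", 1.0), ("m12", 1.2), ("m15", 1.5)), seed=21,
        )
        matrix, _ = simulate_chase(cfg)
        _, summary = run_halflife_pipeline(matrix)
        med = summary["median_halflife_h"]
        assert med["m10"] > med["m12"] > med["m15"]

    def test_empty_matrix_errors(self):
        samples = pd.DataFrame(columns=["condition", "replicate", "time_h"])
        counts = pd.DataFrame()
        m = ChaseCountMatrix(counts, samples, set())
        with pytest.raises(ValueError, match="empty"):
            run_halflife_pipeline(m)

    def test_all_zero_gene_reported_not_quantified(self, tiny_matrix):
        counts = tiny_matrix.counts.copy()
        counts.loc["dead"] = 0
        m = ChaseCountMatrix(counts, tiny_matrix.samples, tiny_matrix.spikein_ids)
        table, _ = run_halflife_pipeline(m)
        assert table.status["dead"] == "not_quantified"

    def test_deterministic_given_fixed_input(self, tiny_matrix):
        t1, s1 = run_halflife_pipeline(tiny_matrix)
        t2, s2 = run_halflife_pipeline(tiny_matrix)
        pd.testing.assert_frame_equal(t1.halflives, t2.halflives)
        assert s1 == s2

    def test_tiny_matrix_exact_values(self, tiny_matrix):
        """The hand-built twofold decayer gives t1/2 = 1 h; the flat gene is
        filtered for non-positive decay."""
        table, summary = run_halflife_pipeline(tiny_matrix)
        assert list(table.halflives.index) == ["fast"]
        assert table.halflives.loc["fast", "c"] == pytest.approx(1.0, abs=1e-12)
        assert table.status["flat"] == "nonpositive_decay"
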
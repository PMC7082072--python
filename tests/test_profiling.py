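import numpy as np
import pytest

from conefate.profiling import (
    classify_cells,
    cluster_cells,
    expressing_s,
    fit_hill,
    fit_m_fraction,
    fit_s_fraction,
    fraction_profile,
    hill_curve,
    intensity_dv_distribution,
    joint_distribution,
    align_tables,
    transition_midpoint,
    transition_stats,
)
from conefate.synthetic import GeneratorParams, generate_cell_table, s_only_probability
from conefate.tables import CellTable


def table_from(y, s, m, length=None, fate=None):
    n = len(y)
    meta = {"strip_length_um": length} if length else {}
    return CellTable.from_arrays(np.zeros(n), y, s, m, fate_truth=fate, metadata=meta)


class TestClassify:
    @pytest.mark.parametrize(
        "s,m,expected",
        [(5.0, 0.0, "S_ONLY"), (5.0, 5.0, "COEXPRESSING"), (0.0, 5.0, "M_ONLY"), (0.5, 0.5, "NONE")],
    )
    def test_label_from_thresholds(self, s, m, expected):
        t = classify_cells(table_from([0.0], [s], [m]), tau_s=1.0, tau_m=1.0)
        assert t.data.class_label[0] == expected

    def test_threshold_monotone_in_tau_s(self, small_table):
        counts = []
        for tau in (1.0, 5.0, 10.0, 50.0, 200.0):
            t = classify_cells(small_table, tau_s=tau)
            counts.append(int(expressing_s(t.data).sum()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_class_counts_match_generator_expectations(self, default_table):
        """Classified S-expressing count agrees with the generator's exact
        threshold-crossing probabilities within a binomial envelope."""
        from conefate.synthetic import implied_s_expressing_fraction
        params = GeneratorParams(seed=11)
        t = classify_cells(default_table)
        n = len(t.data)
        expected = float(np.sum(implied_s_expressing_fraction(params, t.data.y_um.to_numpy())))
        observed = int(expressing_s(t.data).sum())
        sigma = np.sqrt(expected)  # sum of independent Bernoullis
        assert abs(observed - expected) < 5 * sigma


class TestFractionProfile:
    def test_all_satisfying_gives_ones(self):
        t = table_from([10, 20, 30, 40], [50] * 4, [0] * 4, length=100)
        t = classify_cells(t)
        prof = fraction_profile(t, expressing_s, bin_width_um=50.0)
        np.testing.assert_allclose(prof.fraction[prof.valid], 1.0)

    def test_hand_built_two_bin_fractions(self):
        y = [10, 20, 30, 40, 45, 60, 70, 80, 90, 95]
        s = [50, 50, 50, 0, 0, 50, 0, 0, 0, 0]
        t = classify_cells(table_from(y, s, [0] * 10, length=100))
        prof = fraction_profile(t, expressing_s, bin_width_um=50.0)
        np.testing.assert_allclose(prof.fraction, [0.6, 0.2])

    def test_empty_bin_flagged(self):
        t = classify_cells(table_from([10.0, 90.0], [50.0, 50.0], [0, 0], length=150))
        prof = fraction_profile(t, expressing_s, bin_width_um=50.0)
        assert prof.empty[2]
        assert not prof.empty[0] and not prof.empty[1]


class TestFitHill:
    @pytest.mark.parametrize("n_true", [1.0, 2.0, 5.0, 10.0, 30.0, 60.0])
    @pytest.mark.parametrize("direction", ["increasing", "decreasing"])
    def test_noiseless_self_inverse_recovery(self, n_true, direction):
        y = np.linspace(50, 5950, 60)
        v = hill_curve(y, 0.05, 0.9, 2800.0, n_true, direction)
        fit = fit_hill((y, v), direction=direction)
        assert fit.converged and not fit.degenerate
        for got, want in [(fit.base, 0.05), (fit.amplitude, 0.9), (fit.midpoint_um, 2800.0), (fit.n, n_true)]:
            assert abs(got - want) / want < 1e-4

    def test_constant_profile_flagged_degenerate(self):
        y = np.linspace(0, 1000, 20)
        fit = fit_hill((y, np.full(20, 0.5)))
        assert fit.degenerate and not fit.converged

    def test_default_synthetic_retina_coefficients(self, default_table):
        """The mean-retina table reproduces the sharp (~30) S transition and
        gradual (~2-3) M transition."""
        fs = fit_s_fraction(default_table)
        fm = fit_m_fraction(default_table)
        assert 25.0 <= fs.n <= 35.0
        assert 2.0 <= fm.n <= 3.2
        assert fs.n > fm.n

    def test_bootstrap_replicates_bracket_true_coefficient(self):
        """Median fitted S coefficient over noisy replicates is within 25%
        of the underlying transition steepness."""
        rng = np.random.default_rng(0)
        y = np.arange(50, 6000, 100.0)
        truth = hill_curve(y, 0.05, 0.9, 3000.0, 30.0, "increasing")
        n_cells = 300
        ns = []
        for _ in range(50):
            noisy = rng.binomial(n_cells, truth) / n_cells
            ns.append(fit_hill((y, noisy), direction="increasing").n)
        assert abs(np.median(ns) - 30.0) / 30.0 < 0.25


class TestTransitionMidpoint:
    def test_returns_fitted_midpoint(self):
        y = np.linspace(50, 5950, 60)
        fit = fit_hill((y, hill_curve(y, 0.0, 1.0, 3000.0, 30.0)), direction="increasing")
        assert abs(transition_midpoint(fit) - 3000.0) < 1.0

    def test_degenerate_fit_raises(self):
        fit = fit_hill((np.linspace(0, 1000, 20), np.full(20, 0.3)))
        with pytest.raises(ValueError):
            transition_midpoint(fit)


class TestAlign:
    def test_single_table_shift_is_minus_midpoint(self, default_table):
        fit = fit_s_fraction(default_table)
        aligned = align_tables([default_table])[0]
        assert aligned.metadata["y_shift_um"] == pytest.approx(-fit.midpoint_um)

    def test_two_copies_align_identically(self, default_table):
        a, b = align_tables([default_table, default_table.copy()])
        assert a.data.equals(b.data)

    def test_shifted_generators_align_to_zero(self):
        mids = []
        for mid in (2800.0, 3200.0):
            p = GeneratorParams(seed=8, strip_width_um=400.0,
                                s_transition_midpoint_um=mid, s_only_midpoint_um=mid + 300)
            t = generate_cell_table(p)
            aligned = align_tables([t])[0]
            post = fit_s_fraction(aligned)
            mids.append(post.midpoint_um)
        assert all(abs(m) < 60.0 for m in mids)


class TestJointDistribution:
    def test_single_cell_single_occupied_bin(self):
        j = joint_distribution(table_from([0.0], [10.0], [20.0]), n_bins=10)
        assert np.nansum(j.probability) == pytest.approx(1.0)
        assert np.nanmax(j.log10_p) == pytest.approx(0.0)

    def test_probability_normalizes_exactly(self, small_table):
        j = joint_distribution(small_table, n_bins=40)
        assert j.probability.sum() == pytest.approx(1.0)

    def test_ventral_window_shows_two_modes(self, default_table):
        """Ventral of the transition, S-only (high S) and CEC (moderate S)
        populations separate into two occupied intensity regions."""
        df = default_table.data
        win = df[(df.y_um > 4500) & (df.y_um < 6000)]
        s = win.s_intensity.to_numpy()
        hist, edges = np.histogram(s, bins=60, range=(0, 400))
        centers = 0.5 * (edges[:-1] + edges[1:])
        lo_mode = hist[(centers > 30) & (centers < 130)].max()
        hi_mode = hist[(centers > 200) & (centers < 340)].max()
        dip = hist[(centers > 160) & (centers < 200)].min()
        assert lo_mode > 3 * dip and hi_mode > 2 * dip


class TestIntensityDV:
    def test_rows_normalize_to_one(self, default_table):
        _, _, mat = intensity_dv_distribution(default_table, dv_bin_um=500.0)
        sums = mat.sum(axis=1)
        np.testing.assert_allclose(sums[sums > 0], 1.0)

    def test_dorsal_bins_bimodal_in_s(self, default_table):
        """Dorsal S intensity is bimodal: high S-only cones vs near-background CEC."""
        centers, edges, mat = intensity_dv_distribution(default_table, dv_bin_um=1000.0, intensity_bins=80)
        row = mat[0]
        mids = 0.5 * (edges[:-1] + edges[1:])
        low = row[mids < 50].sum()
        high = row[mids > 120].sum()
        gap = row[(mids >= 60) & (mids <= 110)].sum()
        assert low > 0.5 and high > 0.005 and gap < 0.01


class TestCluster:
    def test_two_separated_blobs(self, rng):
        a = rng.normal([50, 50], 3, (500, 2))
        b = rng.normal([300, 300], 3, (500, 2))
        xy = np.vstack([a, b])
        t = CellTable.from_arrays(np.zeros(1000), np.zeros(1000), xy[:, 0], xy[:, 1])
        res = cluster_cells(t, min_cluster_size=50)
        assert res.n_clusters == 2

    def test_single_blob(self, rng):
        xy = rng.normal([100, 100], 5, (600, 2))
        t = CellTable.from_arrays(np.zeros(600), np.zeros(600), xy[:, 0], xy[:, 1])
        res = cluster_cells(t, min_cluster_size=60)
        assert res.n_clusters == 1

    def test_default_table_separates_s_only_from_cec(self, default_table):
        res = cluster_cells(default_table)
        assert res.n_clusters == 2


class TestTransitionStats:
    def test_flat_cec_fraction_gives_zero_slope(self, rng):
        n = 4000
        y = rng.uniform(0, 6000, n)
        fate = np.where(rng.random(n) < 0.8, "CEC", "S_ONLY")
        # S expression: sharp transition so the S fit converges
        s = np.where((y > 3000) | (fate == "S_ONLY"), 100.0, 0.0)
        t = table_from(y, s, np.zeros(n), length=6000, fate=fate)
        st = transition_stats(t)
        assert st.cec_fraction_at_midpoint == pytest.approx(0.8, abs=0.05)
        assert abs(st.cec_slope_at_midpoint) < 2e-5

    def test_matches_generator_interpolant(self, default_table):
        params = GeneratorParams(seed=11)
        st = transition_stats(default_table)
        mid = st.s_midpoint_um
        frac_true = 1.0 - float(s_only_probability(params, mid))
        slope_true = -float(np.diff(s_only_probability(params, [mid - 1, mid + 1]))[0]) / 2.0
        assert abs(st.cec_fraction_at_midpoint - frac_true) < 0.03
        assert st.cec_slope_at_midpoint < 0
        assert abs(st.cec_slope_at_midpoint - slope_true) < 0.5 * abs(slope_true)

    def test_nonconverged_s_fit_raises(self, rng):
        n = 500
        y = rng.uniform(0, 6000, n)
        t = table_from(y, np.full(n, 50.0), np.zeros(n), length=6000)
        with pytest.raises(ValueError):
            transition_stats(t)
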
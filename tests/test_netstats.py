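"""Network aggregation, session and brain-behavior statistics, FDR, power."""

import numpy as np
import pytest

import envconn as ec
from envconn import netstats
from envconn.connectivity import BandConnectivity
from envconn.rois import NetworkTable, all_network_pairs, pairs_of_interest


def _band_conn(matrix, names, networks, band="alpha"):
    return BandConnectivity(
        z={band: matrix}, bands={band: (8.0, 13.0)},
        roi_names=tuple(names), roi_networks=tuple(networks),
    )


def _toy_table(names, networks):
    coords = np.arange(len(names) * 3, dtype=float).reshape(-1, 3) * 20.0
    return NetworkTable(tuple(names), tuple(networks), coords)


class TestAggregation:
    def test_constant_matrix_gives_constant_networks(self, table):
        n = len(table)
        mat = np.full((n, n), 0.42)
        np.fill_diagonal(mat, np.nan)
        bc = _band_conn(mat, table.names, table.networks)
        net = netstats.aggregate_networks(bc, table)
        vals = net.values["alpha"]
        assert np.allclose(vals, 0.42)
        assert np.array_equal(vals, vals.T)

    def test_three_roi_toy_within_mean(self):
        t = _toy_table(["a", "b", "c"], ["MOT"] * 3)
        mat = np.array([
            [np.nan, 0.1, 0.2],
            [0.1, np.nan, 0.6],
            [0.2, 0.6, np.nan],
        ])
        bc = _band_conn(mat, t.names, t.networks)
        net = netstats.aggregate_networks(bc, t)
        assert net.values["alpha"][0, 0] == pytest.approx(0.3)

    def test_sentinel_pairs_excluded_and_counted(self, table):
        n = len(table)
        mat = np.full((n, n), 0.5)
        np.fill_diagonal(mat, np.nan)
        i, j = table.members("MOT")[:2]
        mat[i, j] = mat[j, i] = np.nan
        bc = _band_conn(mat, table.names, table.networks)
        net = netstats.aggregate_networks(bc, table)
        assert net.values["alpha"][net.networks.index("MOT"),
                                   net.networks.index("MOT")] == pytest.approx(0.5)
        assert net.excluded_pairs["alpha"] == 1

    def test_single_roi_within_network_is_an_error(self):
        t = _toy_table(["a", "b", "c"], ["MOT", "MOT", "VIS"])
        mat = np.zeros((3, 3))
        bc = _band_conn(mat, t.names, t.networks)
        with pytest.raises(ValueError, match="fewer than 2"):
            netstats.aggregate_networks(bc, t)

    def test_family_enumeration(self):
        assert len(all_network_pairs()) == 21
        poi = pairs_of_interest()
        assert len(poi) == 6
        assert set(poi) == {("MOT", "MOT"), ("MOT", "DMN"), ("MOT", "DAN"),
                            ("MOT", "VAN"), ("MOT", "VIS"), ("MOT", "LANG")}


class TestSessionEffect:
    def test_no_change_gives_zero_f(self):
        x = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        F, df, p, direction = netstats.session_effect(x, x)
        assert F == 0.0 and direction == 0.0

    def test_df_convention_for_21_subjects(self, rng):
        pre = rng.standard_normal(21)
        post = rng.standard_normal(21)
        _, df, _, _ = netstats.session_effect(pre, post)
        assert df == (1, 20)

    def test_f_equals_squared_paired_t(self, rng):
        pre = rng.standard_normal(5)
        post = pre + 0.3 + 0.2 * rng.standard_normal(5)
        F, _, p, _ = netstats.session_effect(pre, post)
        d = post - pre
        t = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert F == pytest.approx(t**2, abs=1e-10)

    def test_unpaired_subjects_dropped(self):
        pre = np.array([0.1, np.nan, 0.3, 0.4, 0.5])
        post = np.array([0.2, 0.2, 0.4, 0.5, 0.6])
        _, df, _, _ = netstats.session_effect(pre, post)
        assert df == (1, 3)


class TestBrainBehavior:
    def test_perfect_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r, p, n = netstats.brain_behavior_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_toy_vectors_hand_computed(self):
        r, _, n = netstats.brain_behavior_correlation(
            np.array([1.0, 2.0, 3.0, 4.0]), np.array([2.0, 1.0, 4.0, 3.0])
        )
        assert r == pytest.approx(0.6, abs=1e-12)
        assert n == 4

    def test_independent_noise_is_null(self, rng):
        r, _, _ = netstats.brain_behavior_correlation(
            rng.standard_normal(1000), rng.standard_normal(1000)
        )
        assert abs(r) < 0.1

    def test_zero_variance_gives_sentinel(self):
        r, p, n = netstats.brain_behavior_correlation(
            np.ones(6), np.arange(6.0)
        )
        assert np.isnan(r)

    def test_listwise_deletion(self):
        x = np.array([1.0, np.nan, 3.0, 4.0, 5.0, 6.0])
        y = np.array([1.0, 2.0, 3.1, 4.0, np.nan, 6.2])
        _, _, n = netstats.brain_behavior_correlation(x, y)
        assert n == 4


def _brute_force_bh(p, q=0.05):
    """Step-up definition, evaluated literally over all ranks."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p)
    flags = np.zeros(m, bool)
    kmax = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / m:
            kmax = rank
    flags[order[:kmax]] = True
    adj = np.empty(m)
    sorted_adj = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    adj[order] = np.minimum(sorted_adj, 1.0)
    return adj, flags


class TestFDR:
    def test_all_tiny_p_flagged(self):
        adj, flags = netstats.fdr_correct(np.full(6, 0.001))
        assert flags.all()

    def test_single_p_unchanged(self):
        adj, flags = netstats.fdr_correct(np.array([0.03]))
        assert adj[0] == pytest.approx(0.03)

    def test_example_vector_matches_brute_force(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.2, 0.5])
        adj, flags = netstats.fdr_correct(p)
        adj_bf, flags_bf = _brute_force_bh(p)
        assert np.allclose(adj, adj_bf)
        assert np.array_equal(flags, flags_bf)

    def test_adjusted_p_at_least_raw(self, rng):
        p = rng.random(50)
        adj, _ = netstats.fdr_correct(p)
        assert np.all(adj >= p - 1e-12)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            netstats.fdr_correct(np.array([0.1, 1.2]))


class TestCorrelationPower:
    def test_null_power_equals_alpha(self):
        assert netstats.correlation_power_exact(0.0, 20, 0.05) == pytest.approx(
            0.05, abs=1e-4
        )

    def test_density_normalizes(self):
        from scipy.integrate import quad
        total, _ = quad(netstats.sample_correlation_pdf, -1, 1, args=(0.7, 15))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_monotone_in_rho_and_n(self):
        rhos = [0.1, 0.3, 0.5, 0.7, 0.9]
        powers = [netstats.correlation_power_exact(r, 15) for r in rhos]
        assert np.all(np.diff(powers) > 0)
        ns = [6, 10, 20, 40]
        powers_n = [netstats.correlation_power_exact(0.5, n) for n in ns]
        assert np.all(np.diff(powers_n) > 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            netstats.correlation_power_exact(1.0, 10)
        with pytest.raises(ValueError):
            netstats.correlation_power_exact(0.5, 3)
        with pytest.raises(ValueError):
            netstats.correlation_power_exact(0.5, 10, alpha=0.0)


class TestReports:
    def test_fdr_families_attached_per_band(self, rng):
        import pandas as pd
        rows = []
        for band in ("alpha", "beta"):
            for a, b in all_network_pairs():
                rows.append({"band": band, "pair": f"{a}-{b}",
                             "stat": 1.0, "df_or_n": "(1,19)",
                             "p_raw": rng.random()})
        out = netstats._attach_fdr(pd.DataFrame(rows))
        for band in ("alpha", "beta"):
            sub = out[out["band"] == band]
            assert np.isfinite(sub["p_fdr21"]).sum() == 21
            assert np.isfinite(sub["p_fdr6"]).sum() == 6
            assert (sub["p_fdr21"].dropna() >= sub["p_raw"][
                sub["p_fdr21"].notna()] - 1e-12).all()
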
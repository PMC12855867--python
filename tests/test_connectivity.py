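"""Connectivity estimators, IAAFT surrogates, significance, windows, export."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from plasmonet.connectivity import (
    ConnectivityMatrix,
    WindowSpec,
    acc_matrix,
    export_graph,
    global_local_map,
    iaaft_surrogate,
    iaaft_surrogates,
    import_edge_list,
    mean_connectivity_timecourse,
    pearson_matrix,
    plf_matrix,
    significance_filter,
    windowed_connectivity,
)


class TestPearson:
    def test_duplicated_series_gives_one(self, rng):
        x = rng.random(50)
        m = pearson_matrix(np.column_stack([x, x]))
        assert m.weights[0, 1] == pytest.approx(1.0)
        assert m.weights[0, 0] == 0.0

    def test_negative_affine_gives_minus_one(self, rng):
        x = rng.random(50)
        m = pearson_matrix(np.column_stack([x, -2 * x + 5]))
        assert m.weights[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # covariance formula by hand: r((1,2,3,4),(1,3,2,4)) = 4/5
        m = pearson_matrix(np.array([[1, 1], [2, 3], [3, 2], [4, 4]], dtype=float))
        assert m.weights[0, 1] == pytest.approx(0.8, abs=1e-12)

    def test_threshold_zeroes_small_entries(self, rng):
        x = rng.standard_normal(200)
        y = x + 3 * rng.standard_normal(200)
        z = rng.standard_normal(200)
        m = pearson_matrix(np.column_stack([x, y, z]), threshold=0.3)
        raw = pearson_matrix(np.column_stack([x, y, z]))
        assert m.threshold == 0.3
        mask = np.abs(raw.weights) < 0.3
        assert np.all(m.weights[mask] == 0)

    def test_zero_variance_flagged_and_zeroed(self, rng):
        m = pearson_matrix(np.column_stack([rng.random(30), np.full(30, 2.0)]))
        assert m.zero_variance == ["roi2"]
        assert np.all(m.weights == 0)


class TestPLF:
    def test_constant_offset_gives_unity(self, rng):
        th = rng.uniform(0, 2 * np.pi, 500)
        m = plf_matrix(np.column_stack([th, th + 1.234]))
        assert m.weights[0, 1] == pytest.approx(1.0)

    def test_two_sample_cancellation(self):
        phases = np.array([[0.0, 0.0], [0.0, np.pi]])
        m = plf_matrix(phases)
        assert m.weights[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_two_sample_quarter_turn_and_direction(self):
        # phase differences {0, pi/2}: |（1 + i)/2| = sqrt(2)/2, angle pi/4
        phases = np.column_stack([[0.0, np.pi / 2], [0.0, 0.0]])
        und = plf_matrix(phases)
        assert und.weights[0, 1] == pytest.approx(np.sqrt(2) / 2, abs=1e-12)
        d = plf_matrix(phases, directed=True)
        assert d.weights[0, 1] == pytest.approx(np.sqrt(2) / 2, abs=1e-12)
        assert d.weights[1, 0] == 0.0

    def test_matches_direct_summation_oracle(self, rng):
        phases = rng.uniform(0, 2 * np.pi, (1000, 4))
        m = plf_matrix(phases)
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                brute = abs(np.mean(np.exp(1j * (phases[:, i] - phases[:, j]))))
                assert m.weights[i, j] == pytest.approx(brute, abs=1e-12)

    def test_directed_tie_zeroes_both(self):
        # antiphase: mean vector at angle exactly pi for both orderings
        phases = np.column_stack([np.zeros(4), np.full(4, np.pi)])
        d = plf_matrix(phases, directed=True)
        assert d.weights[0, 1] == 0.0 and d.weights[1, 0] == 0.0

    def test_directed_mutual_exclusion(self, rng):
        phases = np.cumsum(rng.standard_normal((500, 5)) * 0.3, axis=0)
        d = plf_matrix(phases, directed=True)
        both = (d.weights != 0) & (d.weights.T != 0)
        assert not both.any()


class TestACC:
    def test_identical_envelopes(self, rng):
        R = rng.random(100) + 1
        m = acc_matrix(np.column_stack([R, R]))
        assert m.weights[0, 1] == pytest.approx(1.0)

    def test_antiscaled_envelope(self, rng):
        R = rng.random(100) + 1
        m = acc_matrix(np.column_stack([R, 5.0 - R]))
        assert m.weights[0, 1] == pytest.approx(-1.0)

    def test_hand_evaluated_covariance(self):
        # direct evaluation of the normalised covariance: sqrt(3)/2
        m = acc_matrix(np.array([[1, 2], [2, 2], [3, 5]], dtype=float))
        assert m.weights[0, 1] == pytest.approx(np.sqrt(3) / 2, abs=1e-12)


class TestIAAFT:
    def test_constant_series_returned_unchanged(self):
        x = np.full(64, 1.5)
        s = iaaft_surrogate(x, seed=0)
        np.testing.assert_array_equal(s, x)

    def test_surrogate_is_exact_permutation(self, rng):
        x = rng.standard_normal(256).cumsum()
        s = iaaft_surrogate(x, seed=3)
        np.testing.assert_array_equal(np.sort(s), np.sort(x))

    def test_spectrum_approaches_original(self, rng):
        phi = 0.9
        eps = rng.standard_normal(1000)
        x = np.empty(1000)
        x[0] = eps[0]
        for i in range(1, 1000):
            x[i] = phi * x[i - 1] + eps[i]
        _, _, mism = iaaft_surrogates(x, 5, np.random.default_rng(1), max_iter=100)
        assert mism.max() < 0.01

    def test_non_finite_input_rejected(self):
        x = np.ones(32)
        x[3] = np.nan
        with pytest.raises(ValueError):
            iaaft_surrogate(x, seed=0)


class TestSignificanceFilter:
    def test_locked_sinusoids_always_retained(self):
        # 5.03 Hz: incommensurate with the sampling grid, so a surrogate
        # cannot reassemble a perfectly locked tone and its PLF stays < 1
        t = np.arange(1000) / 100.0
        x = np.sin(2 * np.pi * 5.03 * t)
        X = np.column_stack([x, np.sin(2 * np.pi * 5.03 * t + 0.7)])
        from scipy.signal import hilbert

        m = plf_matrix(np.angle(hilbert(X, axis=0)))
        f = significance_filter(m, X, rng=0, fs=100.0)
        assert f.weights[0, 1] == pytest.approx(1.0, abs=1e-2)
        assert f.weights[0, 1] != 0
        assert f.significance_filtered

    def test_filter_never_increases_weights(self, rng):
        X = rng.standard_normal((600, 4))
        from scipy.signal import hilbert

        m = plf_matrix(np.angle(hilbert(X, axis=0)))
        f = significance_filter(m, X, n_surrogates=30, rng=1, fs=100.0)
        assert np.all(f.weights <= m.weights + 1e-15)
        assert np.all((f.weights == 0) | (f.weights == m.weights))

    def test_few_surrogates_warns(self, rng):
        X = rng.standard_normal((200, 2))
        m = pearson_matrix(X)
        with pytest.warns(UserWarning, match="surrogates"):
            significance_filter(m, X, n_surrogates=10, rng=0, fs=100.0)


class TestWindows:
    def test_130s_at_10s_1s_gives_121_windows(self):
        spec = WindowSpec(10.0, 1.0)
        assert len(spec.starts(13000, 100.0)) == 121

    def test_windowed_plf_no_trend_for_stationary_coupling(self, rng):
        # constant coupling: the windowed PLF sequence has no trend
        t = np.arange(0, 60, 0.01)
        base = np.cos(2 * np.pi * 5 * t)
        X = np.column_stack([
            base + 0.3 * rng.standard_normal(len(t)),
            np.cos(2 * np.pi * 5 * t + 0.5) + 0.3 * rng.standard_normal(len(t)),
        ])
        mats = windowed_connectivity(X, fs=100.0, method="plf", window=WindowSpec(10, 1))
        series = mean_connectivity_timecourse(mats)
        k = np.arange(len(series))
        slope, intercept = np.polyfit(k, series, 1)
        resid = series - (slope * k + intercept)
        se = np.sqrt(np.sum(resid**2) / (len(k) - 2) / np.sum((k - k.mean()) ** 2))
        assert abs(slope) < 3 * se + 1e-4

    def test_window_shorter_than_trace_required(self, rng):
        with pytest.raises(ValueError, match="shorter"):
            windowed_connectivity(rng.standard_normal((500, 2)), fs=100.0,
                                  window=WindowSpec(10, 1))


class TestMeanTimecourse:
    def test_renormalized_attains_zero_and_one(self, rng):
        mats = [
            ConnectivityMatrix(np.full((3, 3), v), "plf", ["a", "b", "c"])
            for v in (0.2, 0.5, 0.9)
        ]
        out = mean_connectivity_timecourse(mats, renormalize=True)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_degenerate_range_rejected(self):
        mats = [ConnectivityMatrix(np.full((2, 2), 0.4), "plf", ["a", "b"])] * 3
        with pytest.raises(ValueError, match="degenerate"):
            mean_connectivity_timecourse(mats, renormalize=True)

    def test_joint_renormalization_across_conditions(self):
        make = lambda v: ConnectivityMatrix(np.full((2, 2), v), "plf", ["a", "b"])
        out = mean_connectivity_timecourse(
            {"g": [make(0.9), make(0.5)], "n": [make(0.1)]}, renormalize=True
        )
        assert out["g"][0] == 1.0 and out["n"][0] == 0.0


class TestGlobalLocalMap:
    def test_identical_channel_gives_one(self, rng):
        from plasmonet.io_roi import TraceTable

        g = rng.random(100)
        df = pd.DataFrame({"ch1_1": g, "ch1_2": rng.random(100)})
        table = TraceTable(df, 100.0, {}, grid_coords={"ch1_1": (0, 0), "ch1_2": (0, 1)})
        out = global_local_map(g, table)
        assert out[0, 0] == pytest.approx(1.0)

    def test_zero_variance_channel_is_nan(self, rng):
        from plasmonet.io_roi import TraceTable

        g = rng.random(50)
        df = pd.DataFrame({"ch1_1": np.ones(50), "ch1_2": g})
        table = TraceTable(df, 100.0, {}, grid_coords={"ch1_1": (0, 0), "ch1_2": (0, 1)})
        out = global_local_map(g, table)
        assert np.isnan(out[0, 0])
        assert out[0, 1] == pytest.approx(1.0)


class TestGraphExport:
    def test_zero_matrix_exports_no_edges(self, tmp_path):
        m = ConnectivityMatrix(np.zeros((4, 4)), "plf", list("abcd"))
        path = tmp_path / "edges.csv"
        export_graph(m, path)
        assert len(pd.read_csv(path)) == 0

    def test_directed_edge_list_round_trip(self, rng):
        W = np.triu(rng.random((4, 4)), 1)
        m = ConnectivityMatrix(W.copy(), "plf_directed", list("abcd"))
        import tempfile, os

        with tempfile.TemporaryDirectory() as d:
            path = os.path.join(d, "e.csv")
            export_graph(m, path)
            back = import_edge_list(path, list("abcd"), "plf_directed")
        np.testing.assert_array_equal(back.weights, m.weights)

    def test_chain_matrix_exports_chain_ordering(self, tmp_path):
        n = 5
        W = np.zeros((n, n))
        for i in range(n - 1):
            W[i, i + 1] = 0.8
        m = ConnectivityMatrix(W, "plf_directed", [f"cell{i+1}" for i in range(n)])
        path = tmp_path / "chain.csv"
        export_graph(m, path)
        df = pd.read_csv(path)
        assert list(df["source"]) == [f"cell{i+1}" for i in range(n - 1)]
        assert list(df["target"]) == [f"cell{i+2}" for i in range(n - 1)]

    def test_graphml_and_dot_written(self, tmp_path, rng):
        import networkx as nx

        W = np.triu(rng.random((3, 3)), 1)
        m = ConnectivityMatrix(W, "plf_directed", list("xyz"))
        export_graph(m, tmp_path / "g.graphml", "graphml")
        G = nx.read_graphml(tmp_path / "g.graphml")
        assert G.number_of_nodes() == 3
        export_graph(m, tmp_path / "g.dot", "dot")
        text = (tmp_path / "g.dot").read_text()
        assert text.startswith("digraph") and "->" in text


@given(offset=st.floats(-10, 10), data=st.integers(0, 2**31 - 1))
def test_plf_invariant_under_common_phase_offset(offset, data):
    """Adding one constant phase to every channel leaves the PLF unchanged."""
    rng = np.random.default_rng(data)
    phases = rng.uniform(0, 2 * np.pi, (200, 3))
    m1 = plf_matrix(phases)
    m2 = plf_matrix(phases + offset)
    np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-10)
    assert np.all(m1.weights >= 0) and np.all(m1.weights <= 1 + 1e-12)


@given(scale=st.floats(0.1, 50), shift=st.floats(-100, 100), seed=st.integers(0, 2**31 - 1))
def test_pearson_invariant_under_positive_affine_maps(scale, shift, seed):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((100, 3))
    m1 = pearson_matrix(X)
    m2 = pearson_matrix(scale * X + shift)
    np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-9)
    assert np.all(np.abs(m1.weights) <= 1 + 1e-12)


@given(seed=st.integers(0, 2**31 - 1))
def test_surrogate_multiset_is_exact(seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(128)
    s = iaaft_surrogate(x, seed=seed)
    np.testing.assert_array_equal(np.sort(s), np.sort(x))
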
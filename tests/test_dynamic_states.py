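"""State clustering, elbow selection, dwell time, transitions, group stats."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from fncinterp.dynamic_states import (StateModel, cluster_latent, dwell_time,
                                      dwell_time_tests, dynamics_summary,
                                      elbow_point, order_and_match_states,
                                      select_k_elbow, state_group_difference,
                                      state_medians,
                                      state_midpoint_interpolation,
                                      transition_counts, transition_matrix)


def _assign_df(sequences: dict[str, list[int]], groups: dict[str, str]):
    rows = []
    for sid, seq in sequences.items():
        for t, s in enumerate(seq):
            rows.append({"subject_id": sid, "window_index": t,
                         "group": groups[sid], "state": s})
    return pd.DataFrame(rows)


class TestClustering:
    def test_separated_blobs_recovered(self, rng):
        centers = np.array([[-5, 0], [5, 0]])
        labels = rng.integers(0, 2, size=200)
        Z = centers[labels] + rng.normal(scale=0.5, size=(200, 2))
        sm = cluster_latent(Z, k=2, seed=0)
        assert adjusted_rand_score(labels, sm.assignments["state"]) == 1.0

    def test_k_equals_n_zero_inertia(self, rng):
        Z = rng.normal(size=(6, 2))
        sm = cluster_latent(Z, k=6, seed=0, n_init=10)
        assert sm.mean_l2 == pytest.approx(0.0, abs=1e-12)

    def test_seeded_determinism(self, rng):
        Z = rng.normal(size=(100, 2))
        a = cluster_latent(Z, k=3, seed=7)
        b = cluster_latent(Z, k=3, seed=7)
        pd.testing.assert_frame_equal(a.assignments, b.assignments)


class TestElbow:
    def test_constructed_kink(self):
        # convex decreasing with a sharp bend at k=4
        curve = {2: 10.0, 3: 6.0, 4: 3.0, 5: 2.8, 6: 2.7}
        k, warn = elbow_point(curve)
        assert k == 4 and not warn

    def test_planted_five_states(self):
        # five Gaussians, pairwise separation ~6 sigma
        rng = np.random.default_rng(0)
        ang = np.linspace(0, 2 * np.pi, 6)[:5]
        centers = np.column_stack([np.cos(ang), np.sin(ang)]) * 6
        labels = rng.integers(0, 5, size=1500)
        Z = centers[labels] + rng.normal(scale=1.0, size=(1500, 2))
        sm = select_k_elbow(Z, k_range=range(2, 10), seed=0, n_init=10)
        assert sm.k == 5
        assert not sm.elbow_warning

    def test_single_gaussian_warns(self):
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(400, 2))
        with pytest.warns(UserWarning, match="no clear elbow"):
            sm = select_k_elbow(Z, k_range=range(2, 8), seed=0, n_init=5)
        assert sm.elbow_warning

    def test_monotone_flat_curve_returns_smallest(self):
        curve = {2: 5.0, 3: 4.0, 4: 3.0, 5: 2.0}
        k, warn = elbow_point(curve)  # zero second difference everywhere
        assert k == 2 and warn


class TestStateMedians:
    def test_single_member(self, rng):
        X = rng.normal(size=(1, 6))
        df = _assign_df({"s1": [2]}, {"s1": "control"})
        med = state_medians(X, df)
        np.testing.assert_array_equal(med[("control", 2)], X[0])

    def test_symmetric_set_zero_median(self):
        v = np.array([0.5, -0.3, 0.1])
        X = np.vstack([v, -v, np.zeros(3)])
        df = _assign_df({"s1": [1, 1, 1]}, {"s1": "g"})
        np.testing.assert_array_equal(state_medians(X, df)[("g", 1)],
                                      np.zeros(3))

    def test_matches_sort_oracle_seven_members(self, rng):
        X = rng.normal(size=(7, 4))
        df = _assign_df({"s1": [1] * 7}, {"s1": "g"})
        med = state_medians(X, df)[("g", 1)]
        np.testing.assert_array_equal(med, np.sort(X, axis=0)[3])


class TestOrdering:
    def test_control_fraction_sort(self):
        # state 2 has 10% control, state 3 has 50%, state 1 has 90%
        seqs, grp = {}, {}
        for i, (state, n_con, n_pat) in enumerate(
                [(1, 9, 1), (2, 1, 9), (3, 5, 5)]):
            for j in range(n_con):
                sid = f"c{i}_{j}"
                seqs[sid] = [state]
                grp[sid] = "control"
            for j in range(n_pat):
                sid = f"p{i}_{j}"
                seqs[sid] = [state]
                grp[sid] = "patient"
        df = _assign_df(seqs, grp)
        sm = StateModel(k=3, centroids=np.zeros((3, 2)), assignments=df,
                        mean_l2=0.0)
        medians = {(g, s): np.random.default_rng(s).normal(size=5)
                   for g in ("control", "patient") for s in (1, 2, 3)}
        relabel, match = order_and_match_states(sm, medians, medians)
        assert relabel == {2: 1, 3: 2, 1: 3}
        # identical generated/original medians -> matching preserves identity
        for old, new in match.items():
            assert new == relabel[old]

    def test_matching_cost_equals_bruteforce(self, rng):
        for k in (2, 3, 4, 5):
            gen = {("g", s): rng.normal(size=8) for s in range(1, k + 1)}
            orig = {("g", s): rng.normal(size=8) for s in range(1, k + 1)}
            df = _assign_df({f"s{s}": [s] for s in range(1, k + 1)},
                            {f"s{s}": "control" for s in range(1, k + 1)})
            sm = StateModel(k=k, centroids=np.zeros((k, 2)), assignments=df,
                            mean_l2=0.0)
            _, match = order_and_match_states(sm, gen, orig)

            def sim(a, b):
                return np.corrcoef(a, b)[0, 1]

            got = sum(sim(gen[("g", gs)], orig[("g", os_)])
                      for gs, os_ in match.items())
            best = max(
                sum(sim(gen[("g", s)], orig[("g", p[i])])
                    for i, s in enumerate(range(1, k + 1)))
                for p in itertools.permutations(range(1, k + 1))
            )
            assert got == pytest.approx(best, abs=1e-10)


class TestDwellTime:
    def test_hand_example(self):
        df = _assign_df({"s1": [1, 1, 1, 1, 2, 2], "s2": [1, 1, 2, 2, 2, 2]},
                        {"s1": "g", "s2": "g"})
        summ = dwell_time(df)
        dt = summ.dwell.set_index(["group", "state"])["dwell_time"]
        assert dt[("g", 1)] == pytest.approx(6 / 2)  # 4+2 windows, 2 subjects
        assert dt[("g", 2)] == pytest.approx(6 / 2)

    def test_all_windows_one_state(self):
        T = 12
        df = _assign_df({"a": [1] * T, "b": [1] * T}, {"a": "g", "b": "g"})
        summ = dwell_time(df)
        assert summ.dwell.set_index(["group", "state"]).loc[("g", 1),
                                                            "dwell_time"] == T

    def test_window_conservation(self, rng):
        T, n = 50, 8
        seqs = {f"s{i}": list(rng.integers(1, 4, size=T)) for i in range(n)}
        df = _assign_df(seqs, {f"s{i}": "g" for i in range(n)})
        summ = dwell_time(df, k=3)
        assert summ.dwell["n_fnc"].sum() == n * T

    def test_unvisited_state_missing(self):
        df = _assign_df({"a": [1, 1]}, {"a": "g"})
        summ = dwell_time(df, k=2)
        row = summ.dwell.set_index(["group", "state"]).loc[("g", 2)]
        assert row["n_subj"] == 0 and np.isnan(row["dwell_time"])


SEQ = [1, 1, 2, 1, 2, 2, 3]  # 6 transitions


class TestTransitions:
    def test_hand_enumeration(self):
        df = _assign_df({"s": SEQ}, {"s": "g"})
        counts = transition_counts(df, k=3)["g"]
        np.testing.assert_allclose(
            counts,
            np.array([[1, 2, 0], [1, 1, 1], [0, 0, 0]]) / 6.0, atol=1e-12)

    def test_constant_sequence_self_mass_only(self):
        df = _assign_df({"s": [2] * 10}, {"s": "g"})
        counts = transition_counts(df, k=3)["g"]
        assert counts[1, 1] == pytest.approx(1.0)
        assert counts.sum() == pytest.approx(1.0)

    def test_mass_normalization(self, rng):
        seqs = {f"s{i}": list(rng.integers(1, 5, size=30)) for i in range(5)}
        df = _assign_df(seqs, {f"s{i}": "g" for i in range(5)})
        assert transition_counts(df, k=4)["g"].sum() == pytest.approx(1.0)

    def test_probability_matrix_from_hand_counts(self):
        df = _assign_df({"s": SEQ}, {"s": "g"})
        P, flagged = transition_matrix(transition_counts(df, k=3)["g"])
        assert P[0, 1] == pytest.approx(1.0)
        assert P[1, 0] == pytest.approx(0.5)
        assert P[1, 2] == pytest.approx(0.5)
        assert flagged == [2]  # state 3 has no outgoing transitions
        assert np.all(np.isnan(P[2]))

    def test_strict_alternation(self):
        df = _assign_df({"s": [1, 2] * 8}, {"s": "g"})
        P, flagged = transition_matrix(transition_counts(df, k=2)["g"])
        assert P[0, 1] == pytest.approx(1.0)
        assert P[1, 0] == pytest.approx(1.0)
        assert flagged == []

    def test_rows_sum_to_one_diag_zero(self, rng):
        seqs = {f"s{i}": list(rng.integers(1, 6, size=40)) for i in range(6)}
        df = _assign_df(seqs, {f"s{i}": "g" for i in range(6)})
        P, flagged = transition_matrix(transition_counts(df, k=5)["g"])
        assert flagged == []
        np.testing.assert_allclose(np.diag(P), 0.0, atol=1e-12)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_dynamics_summary_bundles_all_parts(self, rng):
        seqs = {f"s{i}": list(rng.integers(1, 4, size=25)) for i in range(4)}
        grp = {f"s{i}": ("patient" if i < 2 else "control") for i in range(4)}
        summ = dynamics_summary(_assign_df(seqs, grp), k=3)
        assert set(summ.counts) == {"patient", "control"}
        for g in summ.P:
            defined = ~np.isnan(summ.P[g]).all(axis=1)
            np.testing.assert_allclose(summ.P[g][defined].sum(axis=1), 1.0,
                                       atol=1e-10)
        # window conservation per group
        per_group = summ.dwell.groupby("group")["n_fnc"].sum()
        assert per_group["patient"] == 2 * 25 and per_group["control"] == 2 * 25


class TestGroupStats:
    def test_planted_edge_difference(self, rng):
        n, V = 100, 60
        a = rng.normal(scale=0.05, size=(n, V))
        b = rng.normal(scale=0.05, size=(n, V))
        a[:, 11] += 0.5
        X = np.vstack([a, b])
        df = _assign_df(
            {f"p{i}": [1] for i in range(n)} | {f"c{i}": [1] for i in range(n)},
            {f"p{i}": "patient" for i in range(n)} |
            {f"c{i}": "control" for i in range(n)})
        # rows of X align with df rows: patients first, then controls
        res = state_group_difference(X, df, state=1)
        assert res["significant"][11]
        assert res["significant"].sum() == 1
        assert res["difference"][11] == pytest.approx(0.5, abs=0.05)

    def test_antisymmetric_under_group_swap(self, rng):
        X = rng.normal(size=(40, 10))
        df = _assign_df(
            {f"p{i}": [1] for i in range(20)} | {f"c{i}": [1] for i in range(20)},
            {f"p{i}": "patient" for i in range(20)} |
            {f"c{i}": "control" for i in range(20)})
        r1 = state_group_difference(X, df, state=1,
                                    groups=("patient", "control"))
        r2 = state_group_difference(X, df, state=1,
                                    groups=("control", "patient"))
        np.testing.assert_allclose(r1["difference"], -r2["difference"],
                                   atol=1e-12)

    def test_absent_group_skipped(self, rng):
        X = rng.normal(size=(5, 4))
        df = _assign_df({f"p{i}": [1] for i in range(5)},
                        {f"p{i}": "patient" for i in range(5)})
        res = state_group_difference(X, df, state=1)
        assert res["skipped"] and res["missing_group"] == "control"


class TestDwellTests:
    @staticmethod
    def _per_subject(rng, shift_state=None, shift=0.0, n=20, k=3):
        rows = []
        for g in ("patient", "control"):
            for i in range(n):
                for s in range(1, k + 1):
                    w = rng.poisson(20)
                    if g == "patient" and s == shift_state:
                        w += shift
                    rows.append({"group": g, "subject_id": f"{g}{i}",
                                 "state": s, "n_windows": w})
        return pd.DataFrame(rows)

    def test_planted_shift_flagged(self, rng):
        df = self._per_subject(rng, shift_state=1, shift=15)
        res = dwell_time_tests(df).set_index("state")
        assert res.loc[1, "p_adjusted"] < 0.05
        assert res.loc[1, "mean_a"] > res.loc[1, "mean_b"]

    def test_bh_stepup_matches_hand_formula(self, rng):
        # force raw p-values {0.01..0.05} through the same adjustment
        from statsmodels.stats.multitest import multipletests
        raw = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        adj = multipletests(raw, method="fdr_bh")[1]
        m = 5
        expected = np.minimum.accumulate(
            (raw * m / np.arange(1, 6))[::-1])[::-1]
        np.testing.assert_allclose(adj, expected, atol=1e-12)

    def test_insufficient_n_skipped(self, rng):
        df = self._per_subject(rng, n=1)
        res = dwell_time_tests(df)
        assert res["skipped"].all()


class TestMidpointInterpolation:
    class _Linear:
        latent_dim = 2

        def __init__(self):
            rng = np.random.default_rng(0)
            self.B = rng.normal(size=(2, 10))

        def decode(self, Z):
            return np.atleast_2d(Z) @ self.B

    def test_identical_centroids_no_edges(self):
        res = state_midpoint_interpolation(self._Linear(), [0.5, 0.5],
                                           [0.5, 0.5], draw_count=20,
                                           noise_scale=0.01, seed=0)
        assert not res["edge_tests"]["significant"].any()

    def test_midpoint_coordinates_exact(self):
        res = state_midpoint_interpolation(self._Linear(), [0.0, 1.0],
                                           [1.0, 0.0], draw_count=3)
        np.testing.assert_allclose(res["points"][1], [0.5, 0.5], atol=1e-12)

    def test_linear_decoder_midpoint_mean(self):
        res = state_midpoint_interpolation(self._Linear(), [-1.0, 0.0],
                                           [1.0, 1.0], draw_count=1)
        a = res["draws"]["a"][0]
        b = res["draws"]["b"][0]
        mid = res["draws"]["midpoint"][0]
        np.testing.assert_allclose(mid, (a + b) / 2, atol=1e-10)
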
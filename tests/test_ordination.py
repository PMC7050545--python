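import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from antplantnet import (
    SpeciesAttributes,
    bray_curtis,
    envfit,
    nmds,
    second_guild_scores,
)
from antplantnet.ordination import ordinate, transform_counts, wisconsin
from antplantnet.synthetic_data import SyntheticConfig, generate_network

from conftest import make_matrix


class TestBrayCurtis:
    def test_hand_example(self):
        d = bray_curtis(np.array([[1, 2], [3, 0]]))
        assert d[0, 1] == pytest.approx(2 / 3)

    def test_identical_rows_zero(self):
        d = bray_curtis(np.array([[2, 4], [2, 4]]))
        assert d[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        d = bray_curtis(np.array([[5, 0], [0, 3]]))
        assert d[0, 1] == 1.0

    def test_symmetric_zero_diagonal_bounded(self, rng):
        w = rng.integers(0, 9, (6, 4)) + (rng.random((6, 4)) < 0.2)
        d = bray_curtis(np.asarray(w, dtype=float) + 0.01)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert d.max() <= 1.0


class TestPava:
    def test_matches_quadratic_program_oracle(self, rng):
        """Isotonic regression equals the projection onto the monotone cone."""
        iso = IsotonicRegression(increasing=True)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            y = rng.standard_normal(n)
            x = np.arange(n, dtype=float)
            fit = iso.fit_transform(x, y)
            cons = [
                {"type": "ineq", "fun": (lambda z, i=i: z[i + 1] - z[i])}
                for i in range(n - 1)
            ]
            qp = minimize(
                lambda z: np.sum((z - y) ** 2), y.copy(), constraints=cons,
                method="SLSQP", options={"maxiter": 500, "ftol": 1e-12},
            )
            assert fit == pytest.approx(qp.x, abs=1e-4)


class TestNmds:
    def test_recovers_planar_configuration(self, rng):
        pts = rng.standard_normal((6, 2))
        d = squareform(pdist(pts))
        res = nmds(d, n_starts=8, rng_seed=0)
        assert res.stress < 1e-3
        assert procrustes(pts, res.plant_scores.to_numpy())[2] < 1e-2

    def test_deterministic_under_seed(self, rng):
        w = rng.integers(0, 8, (8, 5)) + 1
        d = squareform(pdist(w.astype(float), "braycurtis"))
        r1 = nmds(d, n_starts=5, rng_seed=4)
        r2 = nmds(d, n_starts=5, rng_seed=4)
        assert r1.stress == r2.stress
        assert np.array_equal(r1.plant_scores.to_numpy(), r2.plant_scores.to_numpy())

    def test_stress_trace_nonincreasing(self, rng):
        w = rng.integers(0, 8, (10, 6)) + 1
        d = squareform(pdist(w.astype(float), "braycurtis"))
        res = nmds(d, n_starts=3, rng_seed=1)
        tr = res.stress_trace
        assert all(b <= a + 1e-12 for a, b in zip(tr, tr[1:]))

    def test_scores_centered_and_rotated(self, rng):
        w = rng.integers(0, 8, (9, 6)) + 1
        d = squareform(pdist(w.astype(float), "braycurtis"))
        res = nmds(d, n_starts=4, rng_seed=2)
        x = res.plant_scores.to_numpy()
        assert x.mean(axis=0) == pytest.approx([0, 0], abs=1e-9)
        cov = x.T @ x
        assert abs(cov[0, 1]) < 1e-8  # principal axes are uncorrelated
        assert cov[0, 0] >= cov[1, 1]

    def test_shepard_rank_agreement_at_low_stress(self):
        m, _, _ = generate_network(SyntheticConfig(rng_seed=2))
        res = ordinate(m, n_starts=8, rng_seed=0)
        d_in = pdist(transform_counts(m.weights), "braycurtis")
        d_out = pdist(res.plant_scores.to_numpy())
        if res.stress <= 0.2:
            assert stats.spearmanr(d_in, d_out).statistic >= 0.9

    def test_too_few_objects_rejected(self):
        with pytest.raises(ValueError):
            nmds(np.zeros((3, 3)))


class TestSecondGuildScores:
    def test_single_partner_coincides(self):
        m = make_matrix([[2, 1], [0, 3]])
        scores = pd.DataFrame(
            [[1.0, 0.0], [0.0, 1.0]], index=["P1", "P2"], columns=["NMDS1", "NMDS2"]
        )
        ants = second_guild_scores(m, scores)
        # A1 visits only P1
        assert ants.loc["A1"].to_numpy() == pytest.approx([1.0, 0.0])

    def test_weighted_average_split(self):
        m = make_matrix([[1], [3]])
        scores = pd.DataFrame(
            [[0.0, 0.0], [1.0, 1.0]], index=["P1", "P2"], columns=["NMDS1", "NMDS2"]
        )
        ants = second_guild_scores(m, scores)
        assert ants.loc["A1"].to_numpy() == pytest.approx([0.75, 0.75])

    def test_equal_weights_midpoint(self):
        m = make_matrix([[2], [2]])
        scores = pd.DataFrame(
            [[-1.0, 0.0], [1.0, 2.0]], index=["P1", "P2"], columns=["NMDS1", "NMDS2"]
        )
        ants = second_guild_scores(m, scores)
        assert ants.loc["A1"].to_numpy() == pytest.approx([0.0, 1.0])


def _attrs(table: pd.DataFrame) -> SpeciesAttributes:
    return SpeciesAttributes(guild="plant", table=table)


class TestEnvfit:
    def test_perfect_separation_factor(self, rng):
        n = 10
        scores = np.vstack(
            [rng.normal(-5, 0.1, (n, 2)), rng.normal(5, 0.1, (n, 2))]
        )
        labels = [f"s{i}" for i in range(2 * n)]
        df = pd.DataFrame(scores, index=labels, columns=["NMDS1", "NMDS2"])
        attrs = _attrs(
            pd.DataFrame({"grp": ["a"] * n + ["b"] * n}, index=labels)
        )
        rec = envfit(df, attrs, n_perm=999, rng_seed=0)[0]
        assert rec.kind == "factor"
        assert rec.r2 > 0.95
        # a permutation recreating the exact split counts as >= observed,
        # so the attainable minimum is not always 1/(n_perm+1)
        assert rec.p_value <= 0.005

    def test_vector_fit_recovers_gradient(self, rng):
        n = 24
        scores = rng.standard_normal((n, 2))
        labels = [f"s{i}" for i in range(n)]
        df = pd.DataFrame(scores, index=labels, columns=["NMDS1", "NMDS2"])
        attrs = _attrs(pd.DataFrame({"grad": scores[:, 0] * 2 + 1}, index=labels))
        rec = envfit(df, attrs, n_perm=499, rng_seed=0)[0]
        assert rec.kind == "vector"
        assert rec.r2 == pytest.approx(1.0, abs=1e-10)
        assert rec.p_value <= 0.01

    def test_r2_invariant_to_rotation_and_reflection(self, rng):
        n = 16
        scores = rng.standard_normal((n, 2))
        labels = [f"s{i}" for i in range(n)]
        theta = 1.1
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        ) @ np.diag([1, -1])
        attrs = _attrs(
            pd.DataFrame(
                {"grp": list("ab") * (n // 2), "v": rng.standard_normal(n)},
                index=labels,
            )
        )
        r_orig = envfit(
            pd.DataFrame(scores, index=labels, columns=["NMDS1", "NMDS2"]),
            attrs, n_perm=9, rng_seed=0,
        )
        r_rot = envfit(
            pd.DataFrame(scores @ rot, index=labels, columns=["NMDS1", "NMDS2"]),
            attrs, n_perm=9, rng_seed=0,
        )
        for a, b in zip(r_orig, r_rot):
            assert a.r2 == pytest.approx(b.r2)

    def test_single_level_factor_rejected(self, rng):
        labels = ["s0", "s1", "s2", "s3"]
        df = pd.DataFrame(rng.standard_normal((4, 2)), index=labels,
                          columns=["NMDS1", "NMDS2"])
        attrs = _attrs(pd.DataFrame({"grp": ["a"] * 4}, index=labels))
        with pytest.raises(ValueError, match="single level"):
            envfit(df, attrs, n_perm=9, rng_seed=0)

    def test_drop_levels_excludes_mixed_habitat(self, rng):
        labels = [f"s{i}" for i in range(9)]
        df = pd.DataFrame(rng.standard_normal((9, 2)), index=labels,
                          columns=["NMDS1", "NMDS2"])
        attrs = _attrs(pd.DataFrame(
            {"habitat": ["O"] * 4 + ["S"] * 4 + ["B"]}, index=labels))
        rec = envfit(df, attrs, n_perm=9, rng_seed=0,
                     drop_levels={"habitat": {"B"}})[0]
        assert "B" not in rec.detail["centroids"]


class TestTransforms:
    def test_wisconsin_rows_sum_to_one(self, rng):
        w = rng.integers(0, 20, (5, 4)).astype(float) + 1
        t = wisconsin(w)
        assert t.sum(axis=1) == pytest.approx(np.ones(5))
        assert t.max(axis=0).all()

    def test_small_counts_left_raw(self):
        w = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert np.array_equal(transform_counts(w), w)
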
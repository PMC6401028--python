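"""Bray-Curtis, NMDS, and sequential PERMANOVA against independent oracles."""

import shutil
import subprocess
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_bc
from scipy.stats import f_oneway

from reefpulse.community import bray_curtis, nmds, permanova


def dist_from_points(X):
    n = len(X)
    d = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
    return pd.DataFrame(d, index=[f"s{i}" for i in range(n)],
                        columns=[f"s{i}" for i in range(n)])


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        m = pd.DataFrame([[0.2, 0.8], [0.2, 0.8]], index=["a", "b"])
        assert bray_curtis(m).loc["a", "b"] == 0.0

    def test_disjoint_support_one(self):
        m = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"])
        assert bray_curtis(m).loc["a", "b"] == 1.0

    def test_hand_value(self):
        m = pd.DataFrame([[1, 0, 3], [0, 2, 1]], index=["a", "b"], dtype=float)
        assert bray_curtis(m).loc["a", "b"] == pytest.approx(5 / 7)

    def test_matches_scipy_on_random_matrices(self, rng):
        X = rng.random((8, 5))
        m = pd.DataFrame(X, index=[f"s{i}" for i in range(8)])
        d = bray_curtis(m)
        for i, j in combinations(range(8), 2):
            assert d.iloc[i, j] == pytest.approx(scipy_bc(X[i], X[j]))

    def test_all_zero_row_rejected(self):
        m = pd.DataFrame([[0.0, 0.0], [1.0, 0.0]], index=["a", "b"])
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(m)

    def test_negative_rejected(self):
        m = pd.DataFrame([[-0.1, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="non-negative"):
            bray_curtis(m)


class TestNMDS:
    def test_three_equidistant_sites(self):
        d = pd.DataFrame(
            np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float),
            index=list("abc"), columns=list("abc"),
        )
        res = nmds(d, k=2, n_restarts=5, seed=0)
        assert res.stress <= 1e-6

    def test_self_recovery_from_planted_configuration(self, rng):
        X = rng.normal(size=(12, 2))
        res = nmds(dist_from_points(X), k=2, n_restarts=8, seed=0)
        assert res.stress <= 0.01

    def test_stress_nesting_in_dimension(self, rng):
        X = rng.normal(size=(10, 3))
        d = dist_from_points(X)
        s2 = nmds(d, k=2, n_restarts=8, seed=0).stress
        s3 = nmds(d, k=3, n_restarts=8, seed=0).stress
        assert s3 <= s2 + 1e-6

    def test_rank_invariance_under_monotone_transform(self, rng):
        X = rng.normal(size=(9, 2))
        d = dist_from_points(X)
        res_a = nmds(d, n_restarts=8, seed=0)
        res_b = nmds(d**1.7, n_restarts=8, seed=0)  # strictly monotone transform
        assert res_b.stress == pytest.approx(res_a.stress, abs=0.01)

    def test_deterministic_under_fixed_seed(self, rng):
        X = rng.normal(size=(8, 2))
        d = dist_from_points(X)
        a = nmds(d, n_restarts=6, seed=42)
        b = nmds(d, n_restarts=6, seed=42)
        pd.testing.assert_frame_equal(a.coordinates, b.coordinates)
        assert a.stress == b.stress

    def test_too_few_sites_rejected(self):
        d = pd.DataFrame(np.zeros((2, 2)), index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError, match="sites"):
            nmds(d, k=2)


def two_group_oracle_p(d: pd.DataFrame, groups: np.ndarray) -> float:
    """Exhaustive PERMANOVA oracle for one two-level factor: enumerate every
    group assignment of the same sizes and count F* >= F_obs."""
    D = d.to_numpy()
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    n1 = int(groups.sum())

    def f_stat(g):
        x = (g - g.mean())[:, None]
        H = np.hstack([np.ones((n, 1)), x])
        H = H @ np.linalg.pinv(H)
        ss = np.trace(H @ G) - 0  # model SS beyond the mean
        ss_res = np.trace((np.eye(n) - H) @ G)
        return (ss / 1) / (ss_res / (n - 2))

    F_obs = f_stat(groups.astype(float))
    hits = total = 0
    for idx in combinations(range(n), n1):
        g = np.zeros(n)
        g[list(idx)] = 1.0
        total += 1
        if f_stat(g) >= F_obs - 1e-12:
            hits += 1
    return hits / total


class TestPermanova:
    def test_ss_partition_identity(self, rng):
        X = rng.random((10, 4))
        d = bray_curtis(pd.DataFrame(X, index=[f"s{i}" for i in range(10)]))
        factors = pd.DataFrame(
            {"a": rng.normal(size=10), "b": rng.normal(size=10)},
            index=d.index,
        )
        out = permanova(d, factors, n_perm=99, seed=0)
        terms_ss = out.loc[["a", "b"], "SumsOfSqs"].sum()
        assert terms_ss + out.loc["Residuals", "SumsOfSqs"] == pytest.approx(
            out.loc["Total", "SumsOfSqs"], abs=1e-9
        )
        assert out["r2"].drop("Total").sum() == pytest.approx(1.0)

    def test_exact_agreement_with_enumeration_oracle(self, rng):
        # 6 sites, two groups of 3: n! = 720 permutations are enumerated
        X = np.vstack([rng.random((3, 4)), rng.random((3, 4)) + 0.8])
        d = bray_curtis(pd.DataFrame(np.abs(X), index=[f"s{i}" for i in range(6)]))
        groups = np.array([0, 0, 0, 1, 1, 1])
        factors = pd.DataFrame({"g": pd.Categorical(groups.astype(str))}, index=d.index)
        out = permanova(d, factors, n_perm=999, seed=0)
        assert out.attrs["exhaustive"]
        p_oracle = two_group_oracle_p(d, groups)
        assert out.loc["g", "p"] == pytest.approx(p_oracle, abs=1e-12)

    def test_euclidean_one_factor_equals_classical_anova(self, rng):
        # balanced one-factor design on 1-D euclidean distances: the
        # pseudo-F must equal the classical ANOVA F exactly
        y = np.concatenate([rng.normal(0, 1, 5), rng.normal(1.5, 1, 5)])
        d = dist_from_points(y[:, None])
        g = pd.Categorical(["a"] * 5 + ["b"] * 5)
        out = permanova(d, pd.DataFrame({"g": g}, index=d.index), n_perm=99, seed=0)
        F_classic = f_oneway(y[:5], y[5:]).statistic
        assert out.loc["g", "F.model"] == pytest.approx(F_classic, rel=1e-9)

    def test_type_one_error_small(self, rng):
        # scaled-down null calibration; full size in acceptance
        hits = 0
        n_sim = 100
        for s in range(n_sim):
            r = np.random.default_rng(s)
            X = r.random((10, 4))
            d = bray_curtis(pd.DataFrame(X, index=[f"s{i}" for i in range(10)]))
            f = pd.DataFrame({"x": r.normal(size=10)}, index=d.index)
            out = permanova(d, f, n_perm=199, seed=s)
            hits += out.loc["x", "p"] <= 0.05
        assert hits / n_sim < 0.12

    def test_term_order_is_sequential(self, rng):
        # Type-I behavior: the leading term's SS equals its single-term SS,
        # and the summed model SS is order-invariant
        n = 12
        z = rng.normal(size=n)
        x1 = z + rng.normal(0, 0.3, n)
        x2 = z + rng.normal(0, 0.3, n)
        comm = np.abs(z[:, None] + rng.normal(0, 0.4, (n, 4)))
        d = bray_curtis(pd.DataFrame(comm, index=[f"s{i}" for i in range(n)]))
        f = pd.DataFrame({"x1": x1, "x2": x2}, index=d.index)
        a = permanova(d, f, order=["x1", "x2"], n_perm=99, seed=0)
        b = permanova(d, f, order=["x2", "x1"], n_perm=99, seed=0)
        solo = permanova(d, f[["x1"]], n_perm=99, seed=0)
        assert a.loc["x1", "SumsOfSqs"] == pytest.approx(
            solo.loc["x1", "SumsOfSqs"]
        )
        assert a.loc[["x1", "x2"], "SumsOfSqs"].sum() == pytest.approx(
            b.loc[["x1", "x2"], "SumsOfSqs"].sum()
        )

    def test_zero_df_factor_rejected(self):
        d = pd.DataFrame(np.eye(4) * 0 + 0.5 - np.eye(4) * 0.5,
                         index=list("abcd"), columns=list("abcd"))
        f = pd.DataFrame({"g": ["x", "x", "x", "x"]}, index=d.index)
        with pytest.raises(ValueError, match="zero degrees"):
            permanova(d, f, n_perm=99)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_permanova_matches_vegan_adonis2(tmp_path, rng):
    """Cross-check sequential SS, F and r2 against vegan::adonis2."""
    n = 10
    comm = rng.random((n, 5))
    x = rng.normal(size=n)
    g = np.array(["u", "v"] * 5)
    m = pd.DataFrame(comm, index=[f"s{i}" for i in range(n)])
    d = bray_curtis(m)
    factors = pd.DataFrame({"x": x, "g": pd.Categorical(g)}, index=m.index)
    ours = permanova(d, factors, order=["x", "g"], n_perm=999, seed=1)

    m.to_csv(tmp_path / "comm.csv")
    pd.DataFrame({"x": x, "g": g}, index=m.index).to_csv(tmp_path / "fac.csv")
    script = tmp_path / "oracle.R"
    script.write_text(
        """
        suppressMessages(library(vegan))
        comm <- read.csv(commandArgs(TRUE)[1], row.names=1)
        fac <- read.csv(commandArgs(TRUE)[2], row.names=1)
        fac$g <- factor(fac$g)
        res <- adonis2(comm ~ x + g, data=fac, method="bray",
                       permutations=99, by="terms")
        write.csv(as.data.frame(res), commandArgs(TRUE)[3])
        """
    )
    out_csv = tmp_path / "res.csv"
    subprocess.run(
        ["Rscript", str(script), str(tmp_path / "comm.csv"),
         str(tmp_path / "fac.csv"), str(out_csv)],
        check=True, capture_output=True,
    )
    ref = pd.read_csv(out_csv, index_col=0)
    for term in ("x", "g"):
        assert ours.loc[term, "SumsOfSqs"] == pytest.approx(
            ref.loc[term, "SumOfSqs"], rel=1e-6
        )
        assert ours.loc[term, "F.model"] == pytest.approx(ref.loc[term, "F"], rel=1e-6)
        assert ours.loc[term, "r2"] == pytest.approx(ref.loc[term, "R2"], rel=1e-6)
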
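"""Community composition analysis: Bray-Curtis distances, NMDS, sequential PERMANOVA.

Bray-Curtis dissimilarity between composition vectors x, y is
sum|x-y| / sum(x+y).  Non-metric multidimensional scaling finds a low-rank
configuration whose inter-point distances preserve the rank order of the
dissimilarities, minimizing Kruskal stress-1 by alternating isotonic
regression (disparities) with Guttman majorization updates.  PERMANOVA
partitions the Gower-centered inner-product matrix of squared
dissimilarities by sequentially (Type-I) added model terms — continuous
covariates as single-df regression terms, categorical factors dummy-coded —
with pseudo-F significance from unrestricted permutation of observation
rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression


# --- Bray-Curtis -------------------------------------------------------------

def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between rows of a community matrix."""
    X = matrix.to_numpy(float)
    if (X < 0).any():
        raise ValueError("community matrix must be non-negative")
    if (X.sum(axis=1) == 0).any():
        empty = matrix.index[X.sum(axis=1) == 0].tolist()
        raise ValueError(f"all-zero rows (Bray-Curtis undefined): {empty}")
    diff = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    tot = (X[:, None, :] + X[None, :, :]).sum(axis=2)
    d = diff / tot
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


# --- NMDS --------------------------------------------------------------------

@dataclass
class NMDSResult:
    coordinates: pd.DataFrame
    stress: float            # Kruskal stress-1
    n_restarts: int
    converged: bool
    seed: int | None


def _stress1(dist: np.ndarray, disp: np.ndarray) -> float:
    denom = (dist**2).sum()
    if denom == 0:
        return 0.0
    return math.sqrt(((dist - disp) ** 2).sum() / denom)


def _pcoa_start(D: np.ndarray, k: int) -> np.ndarray:
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(G)
    order = np.argsort(w)[::-1][:k]
    w_pos = np.maximum(w[order], 0.0)
    return V[:, order] * np.sqrt(w_pos)


def nmds(
    d: pd.DataFrame,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int | None = 0,
) -> NMDSResult:
    """Non-metric MDS of a dissimilarity matrix, minimizing Kruskal stress-1.

    The first start is the principal-coordinates configuration, the rest are
    random; the best configuration is retained, then centered and rotated to
    its principal axes with each axis's coordinate sum made non-negative so
    output is deterministic under a fixed seed.
    """
    D = d.to_numpy(float)
    n = len(D)
    if n < k + 1:
        raise ValueError(f"need >= {k + 1} sites for k={k}")
    iu = np.triu_indices(n, 1)
    dvec = D[iu]
    order = np.argsort(dvec, kind="stable")
    rng = np.random.default_rng(seed)
    iso = IsotonicRegression(increasing=True)

    best_X, best_stress, any_converged = None, np.inf, False
    scale = dvec.mean() if dvec.mean() > 0 else 1.0
    for r in range(n_restarts):
        X = _pcoa_start(D, k) if r == 0 else rng.normal(scale=scale, size=(n, k))
        last = np.inf
        converged = False
        for _ in range(max_iter):
            dist = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
            dv = dist[iu]
            disp = np.empty_like(dv)
            disp[order] = iso.fit_transform(np.arange(len(dv)), dv[order])
            s = _stress1(dv, disp)
            if abs(last - s) < tol:
                converged = True
                break
            last = s
            # Guttman transform with disparities
            Dhat = np.zeros_like(dist)
            Dhat[iu] = disp
            Dhat = Dhat + Dhat.T
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dist > 0, Dhat / dist, 0.0)
            B = -ratio
            np.fill_diagonal(B, ratio.sum(axis=1))
            X = (B @ X) / n
            X -= X.mean(axis=0)
        if s < best_stress:
            best_stress, best_X = s, X
        any_converged = any_converged or converged

    # canonical orientation: principal axes, non-negative axis sums
    best_X = best_X - best_X.mean(axis=0)
    _, _, Vt = np.linalg.svd(best_X, full_matrices=False)
    best_X = best_X @ Vt.T
    for j in range(k):
        if best_X[:, j].sum() < 0:
            best_X[:, j] *= -1
    coords = pd.DataFrame(
        best_X, index=d.index, columns=[f"NMDS{i+1}" for i in range(k)]
    )
    return NMDSResult(coords, float(best_stress), n_restarts, any_converged, seed)


# --- PERMANOVA ---------------------------------------------------------------

def _gower_center(D: np.ndarray) -> np.ndarray:
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ (D**2) @ J


def _design_columns(factors: pd.DataFrame, order: list[str]):
    """Per-term design columns: centered numeric or dummy-coded categorical."""
    n = len(factors)
    blocks = []
    for name in order:
        col = factors[name]
        if col.isna().any():
            raise ValueError(f"missing values in factor {name!r}")
        if pd.api.types.is_numeric_dtype(col):
            x = col.to_numpy(float)[:, None]
            x = x - x.mean()
            if np.allclose(x, 0):
                raise ValueError(f"factor {name!r} has zero degrees of freedom")
            blocks.append((name, x))
        else:
            levels = sorted(col.unique())
            if len(levels) < 2:
                raise ValueError(f"factor {name!r} has zero degrees of freedom")
            dummies = np.column_stack(
                [(col == lv).to_numpy(float) for lv in levels[1:]]
            )
            blocks.append((name, dummies - dummies.mean(axis=0)))
    return blocks


def _hat(Xc: np.ndarray) -> np.ndarray:
    # projection onto the column space of [1, Xc]
    n = Xc.shape[0]
    X = np.hstack([np.ones((n, 1)), Xc])
    return X @ np.linalg.pinv(X)


def permanova(
    d: pd.DataFrame,
    factors: pd.DataFrame,
    order: list[str] | None = None,
    n_perm: int = 999,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Sequential (Type-I) sums-of-squares PERMANOVA on a distance matrix.

    Terms are added in ``order`` (default: the column order of ``factors``);
    each term's SS is the increase in tr(H G) from adding its columns to the
    cumulative model, with G the Gower-centered inner-product matrix of the
    squared dissimilarities.  Pseudo-F uses the full-model residual; p-values
    come from unrestricted permutation of the observation rows, exhaustively
    enumerated when n! <= n_perm (then p = #{F* >= F}/n!), else Monte Carlo
    with p = (1 + #{F* >= F})/(1 + n_perm).

    Returns a table with rows per term plus Residuals and Total, columns
    ``Df, SumsOfSqs, MeanSqs, F.model, r2, p``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    labels = list(d.index)
    if list(factors.index) != labels:
        factors = factors.loc[labels]
    order = list(order) if order is not None else list(factors.columns)
    D = d.to_numpy(float)
    n = len(D)
    G = _gower_center(D)
    total_ss = float(np.trace(G))

    blocks = _design_columns(factors, order)
    hats, cum = [], np.empty((n, 0))
    dfs = []
    for name, cols in blocks:
        cum = np.hstack([cum, cols])
        H = _hat(cum)
        hats.append(H)
        dfs.append(cols.shape[1])
    H_full = hats[-1]
    df_resid = n - 1 - sum(dfs)
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    R = np.eye(n) - H_full

    def term_stats(Gm):
        prev = 0.0
        ss = []
        for H in hats:
            cur = float(np.sum(H * Gm.T))  # tr(H G)
            ss.append(cur - prev)
            prev = cur
        ss_res = float(np.sum(R * Gm.T))
        Fs = [
            (ss[i] / dfs[i]) / (ss_res / df_resid) for i in range(len(ss))
        ]
        return np.array(ss), ss_res, np.array(Fs)

    ss_obs, ss_res_obs, F_obs = term_stats(G)

    n_total = math.factorial(n)
    rng = np.random.default_rng(seed)
    if n_total <= n_perm:
        count = np.zeros(len(blocks))
        for perm in iter_permutations(range(n)):
            idx = np.array(perm)
            _, _, Fp = term_stats(G[np.ix_(idx, idx)])
            count += Fp >= F_obs - 1e-12
        pvals = count / n_total
    else:
        count = np.zeros(len(blocks))
        for _ in range(n_perm):
            idx = rng.permutation(n)
            _, _, Fp = term_stats(G[np.ix_(idx, idx)])
            count += Fp >= F_obs - 1e-12
        pvals = (1 + count) / (1 + n_perm)

    rows = []
    for i, (name, _) in enumerate(blocks):
        rows.append(
            {"term": name, "Df": dfs[i], "SumsOfSqs": ss_obs[i],
             "MeanSqs": ss_obs[i] / dfs[i], "F.model": F_obs[i],
             "r2": ss_obs[i] / total_ss, "p": pvals[i]}
        )
    rows.append(
        {"term": "Residuals", "Df": df_resid, "SumsOfSqs": ss_res_obs,
         "MeanSqs": ss_res_obs / df_resid, "F.model": np.nan,
         "r2": ss_res_obs / total_ss, "p": np.nan}
    )
    rows.append(
        {"term": "Total", "Df": n - 1, "SumsOfSqs": total_ss,
         "MeanSqs": np.nan, "F.model": np.nan, "r2": 1.0, "p": np.nan}
    )
    out = pd.DataFrame(rows).set_index("term")
    out.attrs["n_perm"] = n_perm if n_total > n_perm else n_total
    out.attrs["exhaustive"] = n_total <= n_perm
    out.attrs["seed"] = seed
    return out
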
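"""Penalized additive models with shrinkage splines, and AICc model comparison.

Smooth terms use a natural cubic regression spline basis (values-at-knots
parameterization, knots at quantiles of the covariate) with the integrated
squared second derivative as penalty.  The penalty is eigen-modified so that
its null space (the linear component) is also weakly penalized: as the
smoothing parameter grows a term shrinks smoothly through linear to zero,
allowing the smoother itself to drop irrelevant covariates.  Smoothing
parameters are chosen per term by generalized cross-validation (GCV) via
coordinate descent on a log grid.  Basis dimension defaults to k = 3 per
smooth, deliberately small to limit overfitting on site-level sample sizes.

Model quality is reported as deviance explained, adjusted r^2, GCV, and the
small-sample AICc; nested models are compared with an analysis-of-deviance
F-test on residual deviance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

SHRINKAGE_EPS = 0.1      # null-space eigenvalues as a fraction of the
                         # smallest positive penalty eigenvalue
LAMBDA_GRID = np.logspace(-7, 9, 49)
GCV_GAMMA = 1.4          # effective-df inflation in the GCV denominator,
                         # the standard guard against GCV undersmoothing


# --- natural cubic spline basis ---------------------------------------------

def _ncs_matrices(knots: np.ndarray):
    """Penalty building blocks for a natural cubic spline with given knots.

    Returns (F, S): F maps values-at-knots to second derivatives at all
    knots (endpoint rows zero); S = D' B^{-1} D is the integrated squared
    second-derivative penalty.
    """
    k = len(knots)
    h = np.diff(knots)
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i < k - 3:
            B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
    Binv = np.linalg.inv(B)
    F = np.zeros((k, k))
    F[1:-1, :] = Binv @ D
    S = D.T @ Binv @ D
    return F, S


def ncs_basis(x: np.ndarray, knots: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Evaluate the k natural-cubic-spline cardinal basis functions at x.

    x outside the knot range is extended linearly (natural boundary).
    """
    k = len(knots)
    h = np.diff(knots)
    x = np.asarray(x, dtype=float)
    xc = np.clip(x, knots[0], knots[-1])
    j = np.clip(np.searchsorted(knots, xc, side="right") - 1, 0, k - 2)
    hj = h[j]
    lo, hi = knots[j], knots[j + 1]
    am = (hi - xc) / hj
    ap = (xc - lo) / hj
    cm = ((hi - xc) ** 3 / hj - hj * (hi - xc)) / 6.0
    cp = ((xc - lo) ** 3 / hj - hj * (xc - lo)) / 6.0
    n = len(x)
    A = np.zeros((n, k))
    C = np.zeros((n, k))
    rows = np.arange(n)
    A[rows, j] += am
    A[rows, j + 1] += ap
    C[rows, j] += cm
    C[rows, j + 1] += cp
    X = A + C @ F
    # linear extension beyond the boundary knots
    out_lo = x < knots[0]
    out_hi = x > knots[-1]
    if out_lo.any() or out_hi.any():
        eps = 1e-6 * (knots[-1] - knots[0])
        for mask, x0 in ((out_lo, knots[0]), (out_hi, knots[-1])):
            if mask.any():
                b0 = ncs_basis(np.array([x0]), knots, F)
                b1 = ncs_basis(np.array([x0 + (eps if x0 == knots[0] else -eps)]), knots, F)
                slope = (b1 - b0) / (eps if x0 == knots[0] else -eps)
                X[mask] = b0 + (x[mask] - x0)[:, None] * slope
    return X


def _tp_basis(x: np.ndarray, knots: np.ndarray):
    """1-D thin-plate-style radial basis |x - knot|^3 with a ridge penalty;
    alternative basis for sensitivity checks."""
    X = np.abs(x[:, None] - knots[None, :]) ** 3
    scale = (knots[-1] - knots[0]) ** 3
    X = X / scale
    S = np.eye(len(knots))
    return X, S


# --- term and fit containers -------------------------------------------------

@dataclass
class _Term:
    name: str
    kind: str                   # "smooth", "linear", "interaction"
    cols: slice = field(default=None)
    knots: np.ndarray | None = None
    F: np.ndarray | None = None
    S: np.ndarray | None = None  # penalty in the constrained parameterization
    Z: np.ndarray | None = None  # constraint null-space basis
    center: float = 0.0
    scale: float = 1.0
    vars: tuple = ()


@dataclass
class ModelFitSummary:
    """Fitted additive/linear model with selection statistics.

    AICc is the second-order criterion AIC + 2k(k+1)/(n-k-1) with k the
    effective number of parameters (total edf + 1 for the scale).
    """

    terms: list
    n: int
    edf: dict
    edf_total: float
    deviance: float          # residual sum of squares (gaussian deviance)
    null_deviance: float
    deviance_explained: float
    r2_adj: float
    gcv: float
    aicc: float
    p_value: float
    lambdas: dict
    coef: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    y: np.ndarray
    term_signs: dict
    term_slopes: dict        # original-scale slope for linear terms
    basis: str = "cr"

    @property
    def aic(self) -> float:
        k = self.edf_total + 1.0
        return self.aicc - 2 * k * (k + 1) / (self.n - k - 1)


def aicc_from_loglik(loglik: float, n: int, k: float) -> float:
    """Second-order AIC: -2*loglik + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError("AICc undefined: n <= k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def _gaussian_loglik(rss: float, n: int) -> float:
    return -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)


# --- model construction ------------------------------------------------------

def _build_design(
    table: pd.DataFrame,
    smooth: list[str],
    linear: list[str],
    interactions: list[tuple[str, str]],
    k: int,
    basis: str,
):
    n = len(table)
    cols = [np.ones((n, 1))]
    terms: list[_Term] = []
    pos = 1
    stats_ = {}
    for v in list(smooth) + list(linear) + [a for pair in interactions for a in pair]:
        if v not in table.columns:
            raise KeyError(f"term variable {v!r} not in table")
        x = table[v].to_numpy(float)
        if np.isnan(x).any():
            raise ValueError(f"missing values in {v!r}")
        stats_[v] = (x.mean(), x.std(ddof=0) or 1.0)

    for v in smooth:
        mu, sd = stats_[v]
        z = (table[v].to_numpy(float) - mu) / sd
        qs = np.linspace(0, 1, k)
        knots = np.quantile(z, qs)
        if len(np.unique(knots)) < k:
            raise ValueError(f"smooth term {v!r}: too few distinct values for k={k}")
        if basis == "cr":
            F, S = _ncs_matrices(knots)
            X = ncs_basis(z, knots, F)
        elif basis == "tp":
            X, S = _tp_basis(z, knots)
            F = None
        else:
            raise ValueError(f"unknown basis {basis!r}")
        # absorb the sum-to-zero constraint: 1'X beta = 0
        C = X.sum(axis=0, keepdims=True)
        q, _ = np.linalg.qr(C.T, mode="complete")
        Z = q[:, 1:]
        Xc = X @ Z
        Sc = Z.T @ S @ Z
        # eigen-shrinkage: weakly penalize the (linear) null space so the
        # term can shrink to zero entirely
        w, U = np.linalg.eigh(Sc)
        w = np.maximum(w, 0.0)
        pos_w = w[w > 1e-10 * w.max()] if w.max() > 0 else np.array([1.0])
        floor = SHRINKAGE_EPS * pos_w.min()
        w = np.where(w < floor, floor, w)
        Sc = U @ np.diag(w) @ U.T
        Sc = Sc / np.linalg.norm(Sc)  # unit-norm penalty -> comparable lambdas
        terms.append(
            _Term(f"s({v})", "smooth", slice(pos, pos + Xc.shape[1]),
                  knots, F, Sc, Z, mu, sd, (v,))
        )
        cols.append(Xc)
        pos += Xc.shape[1]

    for v in linear:
        mu, sd = stats_[v]
        z = ((table[v].to_numpy(float) - mu) / sd)[:, None]
        terms.append(_Term(v, "linear", slice(pos, pos + 1), center=mu, scale=sd, vars=(v,)))
        cols.append(z)
        pos += 1

    for a, b in interactions:
        za = (table[a].to_numpy(float) - stats_[a][0]) / stats_[a][1]
        zb = (table[b].to_numpy(float) - stats_[b][0]) / stats_[b][1]
        prod = (za * zb)[:, None]
        prod = prod - prod.mean()
        terms.append(_Term(f"{a}:{b}", "interaction", slice(pos, pos + 1), vars=(a, b)))
        cols.append(prod)
        pos += 1

    X = np.hstack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify terms whose columns add no rank
        bad, r_prev = [], np.linalg.matrix_rank(X[:, :1])
        for t in terms:
            r_now = np.linalg.matrix_rank(X[:, : t.cols.stop])
            if r_now - r_prev < (t.cols.stop - t.cols.start):
                bad.append(t.name)
            r_prev = r_now
        raise np.linalg.LinAlgError(f"rank-deficient design; collinear terms: {bad}")
    return X, terms


def _penalty(terms, lambdas, p):
    S = np.zeros((p, p))
    for t in terms:
        if t.kind == "smooth":
            S[t.cols, t.cols] += lambdas[t.name] * t.S
    return S


def _solve(X, y, S):
    A = X.T @ X + S
    beta = np.linalg.solve(A, X.T @ y)
    # edf per coefficient: diag(A^{-1} X'X)
    edf_diag = np.diag(np.linalg.solve(A, X.T @ X))
    fitted = X @ beta
    rss = float(((y - fitted) ** 2).sum())
    return beta, fitted, rss, edf_diag


def fit_response_model(
    table: pd.DataFrame,
    response: str,
    smooth: list[str] = (),
    linear: list[str] = (),
    interactions: list[tuple[str, str]] = (),
    k: int = 3,
    basis: str = "cr",
    family: str = "gaussian",
    n_sweeps: int = 3,
    gcv_gamma: float = GCV_GAMMA,
) -> ModelFitSummary:
    """Fit a penalized additive model and report selection statistics.

    Parameters
    ----------
    table : DataFrame
        Per-site predictor table containing the response and all terms.
    response : str
        Response column (e.g. a bleaching response index).
    smooth, linear : lists of column names
        Terms entering as shrinkage smooths (basis dimension ``k``) or as
        unpenalized linear effects.
    interactions : list of (a, b) pairs
        Pairwise product terms (centered), for GLM-style interactive effects.
    basis : "cr" or "tp"
        Cubic regression spline (default) or thin-plate-style radial basis.
    """
    if family != "gaussian":
        raise NotImplementedError("only the gaussian/identity family is implemented")
    y = table[response].to_numpy(float)
    if np.isnan(y).any():
        raise ValueError("missing values in response")
    n = len(y)
    X, terms = _build_design(table, list(smooth), list(linear), list(interactions), k, basis)
    p = X.shape[1]
    if n <= p + 1:
        raise ValueError(f"n={n} too small for {p} coefficients")

    smooth_terms = [t for t in terms if t.kind == "smooth"]
    lambdas = {t.name: 1.0 for t in smooth_terms}

    def gcv_of(lams):
        S = _penalty(terms, lams, p)
        _, _, rss, edf_diag = _solve(X, y, S)
        edf_tot = float(edf_diag.sum())
        return n * rss / (n - gcv_gamma * edf_tot) ** 2

    if smooth_terms:
        for _ in range(n_sweeps):
            for t in smooth_terms:
                best_lam, best_gcv = lambdas[t.name], np.inf
                for lam in LAMBDA_GRID:
                    trial = {**lambdas, t.name: lam}
                    g = gcv_of(trial)
                    if g < best_gcv - 1e-12:
                        best_gcv, best_lam = g, lam
                lambdas[t.name] = best_lam

    S = _penalty(terms, lambdas, p)
    beta, fitted, rss, edf_diag = _solve(X, y, S)
    edf_tot = float(edf_diag.sum())
    edf = {t.name: float(edf_diag[t.cols].sum()) for t in terms}
    null_dev = float(((y - y.mean()) ** 2).sum())
    dev_expl = 1.0 - rss / null_dev if null_dev > 0 else 0.0
    resid_df = n - edf_tot
    r2_adj = 1.0 - (rss / resid_df) / (null_dev / (n - 1)) if resid_df > 0 else np.nan
    gcv = n * rss / (n - gcv_gamma * edf_tot) ** 2
    aicc = aicc_from_loglik(_gaussian_loglik(rss, n), n, edf_tot + 1.0)
    # overall model F-test against the intercept-only null
    num_df = max(edf_tot - 1.0, 1e-8)
    if null_dev > rss and resid_df > 0:
        F = ((null_dev - rss) / num_df) / (rss / resid_df)
        p_val = float(sps.f.sf(F, num_df, resid_df))
    else:
        p_val = 1.0

    signs, slopes = {}, {}
    for t in terms:
        partial = X[:, t.cols] @ beta[t.cols]
        if t.kind in ("linear",):
            slopes[t.name] = float(beta[t.cols][0] / t.scale)
            signs[t.name] = float(np.sign(slopes[t.name]))
        else:
            xv = table[t.vars[0]].to_numpy(float)
            # a term shrunk to (numerically) zero carries no sign
            if np.std(partial) > 1e-8 * max(np.std(y), 1e-12):
                signs[t.name] = float(np.sign(np.corrcoef(xv, partial)[0, 1]))
            else:
                signs[t.name] = 0.0
    return ModelFitSummary(
        terms=[t.name for t in terms],
        n=n,
        edf=edf,
        edf_total=edf_tot,
        deviance=rss,
        null_deviance=null_dev,
        deviance_explained=dev_expl,
        r2_adj=float(r2_adj),
        gcv=float(gcv),
        aicc=float(aicc),
        p_value=p_val,
        lambdas=lambdas,
        coef=beta,
        fitted=fitted,
        residuals=y - fitted,
        y=y,
        term_signs=signs,
        term_slopes=slopes,
        basis=basis,
    )


# --- model comparison --------------------------------------------------------

def compare_models(
    fits: dict[str, ModelFitSummary],
    nested_pairs: list[tuple[str, str]] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank fitted models by AICc and run analysis-of-deviance F-tests.

    ``nested_pairs`` lists (smaller, larger) model names sharing a response;
    the F statistic is the deviance drop per added edf over the larger
    model's residual mean deviance.  A pair whose larger model does not
    reduce deviance reports F = 0, p = 1.
    """
    names = list(fits)
    ys = [fits[n].y for n in names]
    for other in ys[1:]:
        if len(other) != len(ys[0]) or not np.allclose(other, ys[0]):
            raise ValueError("models being compared must share the same response")
    rank_df = pd.DataFrame(
        {
            "aicc": [fits[n].aicc for n in names],
            "deviance_explained": [fits[n].deviance_explained for n in names],
            "edf": [fits[n].edf_total for n in names],
            "gcv": [fits[n].gcv for n in names],
        },
        index=pd.Index(names, name="model"),
    ).sort_values("aicc", kind="stable")
    rank_df["delta_aicc"] = rank_df["aicc"] - rank_df["aicc"].iloc[0]
    rank_df["rank"] = rank_df["aicc"].rank(method="min").astype(int)

    rows = []
    for small, large in nested_pairs:
        fs, fl = fits[small], fits[large]
        ddf = fl.edf_total - fs.edf_total
        resid_df = fl.n - fl.edf_total
        ddev = fs.deviance - fl.deviance
        if ddev <= 0 or ddf <= 0:
            F, pv = 0.0, 1.0
        else:
            F = (ddev / ddf) / (fl.deviance / resid_df)
            pv = float(sps.f.sf(F, ddf, resid_df))
        rows.append(
            {"smaller": small, "larger": large, "ddf": ddf,
             "deviance_drop": ddev, "F": F, "p_value": pv}
        )
    return rank_df, pd.DataFrame(rows)
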
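"""Univariate inference: normality-gated two-sample tests and Bonferroni screening.

Two-sample comparisons are gated on the Shapiro-Wilk test: when both samples
look normal at the gate level, Welch's unequal-variance t-test is used;
otherwise a two-sided permutation test on the difference in group means,
exact (full enumeration of group assignments) when feasible and Monte Carlo
otherwise.  The univariate screen regresses a response on each candidate
predictor separately and flags significance at Bonferroni-corrected levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_LIMIT = 100_000  # max distinct group assignments for full enumeration


@dataclass(frozen=True)
class TwoSampleResult:
    method: str          # "welch_t" or "permutation"
    statistic: float     # t for Welch, mean difference for permutation
    p_value: float
    n1: int
    n2: int
    shapiro_p: tuple[float, float]
    exact: bool = False
    n_perm: int | None = None


def _shapiro_p(x: np.ndarray) -> float:
    # constant samples are degenerate, route them to the permutation branch
    if np.ptp(x) == 0:
        return 0.0
    return float(sps.shapiro(x).pvalue)


def two_sample_test(
    x,
    y,
    gate_alpha: float = 0.05,
    B: int = 9999,
    seed: int | None = None,
    paired: bool = False,
) -> TwoSampleResult:
    """Two-sided difference-in-means test with a Shapiro-Wilk normality gate.

    Exact permutation p-values count the fraction of all C(n1+n2, n1) group
    assignments with |mean difference| >= observed (no +1 correction; the
    observed assignment is one of the enumerated ones).  Monte Carlo uses
    p = (1 + #{|d*| >= |d|}) / (1 + B).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 3 or n2 < 3:
        raise ValueError(f"need >= 3 observations per sample, got {n1}, {n2}")
    if paired:
        raise ValueError("paired comparisons are not supported")

    sp = (_shapiro_p(x), _shapiro_p(y))
    d_obs = x.mean() - y.mean()

    if np.ptp(x) == 0 and np.ptp(y) == 0 and d_obs == 0:
        return TwoSampleResult("permutation", 0.0, 1.0, n1, n2, sp, exact=True)

    if sp[0] >= gate_alpha and sp[1] >= gate_alpha:
        t, p = sps.ttest_ind(x, y, equal_var=False)
        return TwoSampleResult("welch_t", float(t), float(p), n1, n2, sp)

    pooled = np.concatenate([x, y])
    total = math.comb(n1 + n2, n1)
    tol = 1e-12 * max(1.0, abs(d_obs))
    if total <= EXACT_LIMIT:
        grand = pooled.sum()
        hits = 0
        for idx in combinations(range(n1 + n2), n1):
            m1 = pooled[list(idx)].sum() / n1
            m2 = (grand - pooled[list(idx)].sum()) / n2
            if abs(m1 - m2) >= abs(d_obs) - tol:
                hits += 1
        return TwoSampleResult(
            "permutation", float(d_obs), hits / total, n1, n2, sp,
            exact=True, n_perm=total,
        )
    rng = np.random.default_rng(seed)
    # vectorized Monte Carlo: each row of perms is a shuffled pooled sample
    hits = 0
    chunk = 2000
    done = 0
    while done < B:
        b = min(chunk, B - done)
        perm = rng.permuted(
            np.broadcast_to(pooled, (b, n1 + n2)).copy(), axis=1
        )
        d = perm[:, :n1].mean(axis=1) - perm[:, n1:].mean(axis=1)
        hits += int((np.abs(d) >= abs(d_obs) - tol).sum())
        done += b
    p = (1 + hits) / (1 + B)
    return TwoSampleResult(
        "permutation", float(d_obs), p, n1, n2, sp, exact=False, n_perm=B
    )


# --- univariate screening ----------------------------------------------------

SCREEN_ALPHAS = (0.01, 0.05, 0.10)


@dataclass(frozen=True)
class ScreenRow:
    predictor: str
    R: float             # correlation, carrying the slope's sign
    RMSE: float          # root mean squared residual, response units
    slope: float
    p_raw: float
    n: int
    degenerate: bool = False

    def significant(self, alpha: float, m: int, bonferroni: bool = True) -> bool:
        level = alpha / m if bonferroni else alpha
        return (not self.degenerate) and self.p_raw < level


def univariate_screen(
    response: pd.Series,
    predictors: pd.DataFrame,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Simple least-squares regression of the response on each predictor.

    Returns one row per predictor with signed correlation R, RMSE, slope and
    raw p (slope t-test), plus Bonferroni flags at alpha/m for alpha in
    {0.01, 0.05, 0.10}; m defaults to the number of predictors screened and
    is recorded in ``attrs['family_size']``.  Constant predictors yield a
    degenerate row (R = 0) rather than an error.
    """
    cols = list(predictors.columns)
    m = family_size if family_size is not None else len(cols)
    rows = []
    for name in cols:
        merged = pd.concat([response.rename("y"), predictors[name]], axis=1).dropna()
        yv = merged["y"].to_numpy(float)
        xv = merged[name].to_numpy(float)
        n = len(yv)
        if n < 4:
            raise ValueError(f"predictor {name!r}: only {n} complete cases (< 4)")
        if np.ptp(xv) == 0:
            rows.append(
                ScreenRow(name, 0.0, float(np.sqrt(np.mean((yv - yv.mean()) ** 2))),
                          0.0, 1.0, n, degenerate=True)
            )
            continue
        fit = sps.linregress(xv, yv)
        resid = yv - (fit.intercept + fit.slope * xv)
        rows.append(
            ScreenRow(
                name,
                float(fit.rvalue),
                float(np.sqrt(np.mean(resid**2))),
                float(fit.slope),
                float(fit.pvalue),
                n,
            )
        )
    out = pd.DataFrame([r.__dict__ for r in rows]).set_index("predictor")
    for a in SCREEN_ALPHAS:
        out[f"sig_raw_{a:g}"] = (out["p_raw"] < a) & ~out["degenerate"]
        out[f"sig_bonf_{a:g}"] = (out["p_raw"] < a / m) & ~out["degenerate"]
    out.attrs["family_size"] = m
    return out
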
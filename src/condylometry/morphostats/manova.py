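"""Pillai's-trace MANOVA, Box's M, and the Pearson collinearity screen.

The MANOVA is computed from hypothesis (H) and error (E) cross-product
matrices. For each effect, Pillai's trace is ``V = tr(H(H+E)^{-1})`` and
its approximate F uses the classical (s, m, n) parameterization

    s  = min(p, q),   m = (|p − q| − 1)/2,   n = (df_error − p − 1)/2,
    F  = ((2n + s + 1)/(2m + s + 1)) · (V/s)/(1 − V/s),
    df1 = s(2m + s + 1),   df2 = s(2n + s + 1),

with ``p`` response variables and ``q`` hypothesis degrees of freedom.
One-way designs test the single group effect; two-way designs with
interaction use Type III hypotheses on a sum-to-zero (effect) coding,
appropriate for unbalanced cell counts. Partial eta-squared is reported
as ``V/s``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import f as f_dist

from ..errors import RankDeficiencyError


@dataclass(frozen=True)
class ManovaResult:
    """Pillai-trace test of one effect."""

    effect: str
    pillai: float
    F: float
    df1: int
    df2: int
    p: float
    partial_eta2: float
    s: int
    m: float
    n: float


def _as_matrix(data):
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.columns)
    arr = np.asarray(data, dtype=float)
    return arr, [f"x{i}" for i in range(arr.shape[1])]


def _check_rank(mat: np.ndarray, names) -> None:
    if np.linalg.matrix_rank(mat) < mat.shape[0]:
        # name near-degenerate columns to help the caller
        d = np.sqrt(np.diag(mat))
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = mat / np.outer(d, d)
        low_var = [names[i] for i in range(len(names)) if d[i] < 1e-10]
        dup = [f"{names[i]}~{names[j]}"
               for i in range(len(names)) for j in range(i + 1, len(names))
               if abs(corr[i, j]) > 1 - 1e-10]
        raise RankDeficiencyError(
            "singular cross-product matrix; offending variables: "
            f"zero-variance={low_var or 'none'}, collinear={dup or 'none'}")


def _effect_coding(labels: np.ndarray) -> tuple:
    """Sum-to-zero coded columns (g−1) for a factor; last level is the
    reference."""
    levels = list(pd.unique(labels))
    g = len(levels)
    X = np.zeros((len(labels), g - 1))
    for j, lev in enumerate(levels[:-1]):
        X[labels == lev, j] = 1.0
    X[labels == levels[-1], :] = -1.0
    return X, levels


def _pillai_from_he(effect, H, E, p, q, df_error, names):
    _check_rank(H + E, names)
    V = float(np.trace(H @ np.linalg.inv(H + E)))
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    n = (df_error - p - 1) / 2.0
    df1 = int(round(s * (2 * m + s + 1)))
    df2 = int(round(s * (2 * n + s + 1)))
    ratio = (V / s) / (1 - V / s)
    F = (2 * n + s + 1) / (2 * m + s + 1) * ratio
    pval = float(f_dist.sf(F, df1, df2))
    return ManovaResult(effect=effect, pillai=V, F=float(F), df1=df1,
                        df2=df2, p=pval, partial_eta2=V / s, s=s, m=m, n=n)


def pillai_manova(data, groups: Optional[Sequence] = None,
                  factors: Optional[tuple] = None) -> list:
    """Pillai's-trace MANOVA; one-way (``groups``) or two-way with
    interaction (``factors=(a, b)``).

    Returns one :class:`ManovaResult` per effect; for the two-way design
    the effects are the two main effects (Type III) and their interaction.
    Requires every cell to be non-empty and ``n`` exceeding the number of
    model parameters.
    """
    Y, names = _as_matrix(data)
    n_obs, p = Y.shape
    if (groups is None) == (factors is None):
        raise ValueError("pass exactly one of groups= or factors=")

    if groups is not None:
        labels = np.asarray(groups)
        Xg, levels = _effect_coding(labels)
        if any((labels == lev).sum() == 0 for lev in levels):
            raise ValueError("empty group")
        blocks = {"group": Xg}
    else:
        fa, fb = (np.asarray(f) for f in factors)
        Xa, lev_a = _effect_coding(fa)
        Xb, lev_b = _effect_coding(fb)
        for la in lev_a:
            for lb in lev_b:
                if not np.any((fa == la) & (fb == lb)):
                    raise ValueError(f"empty cell ({la}, {lb})")
        Xab = np.column_stack([Xa[:, i] * Xb[:, j]
                               for i in range(Xa.shape[1])
                               for j in range(Xb.shape[1])])
        blocks = {"factor_a": Xa, "factor_b": Xb, "interaction": Xab}

    X = np.column_stack([np.ones(n_obs)] + list(blocks.values()))
    k = X.shape[1]
    if n_obs <= k + p:
        raise ValueError("too few observations for the design")
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < k:
        raise RankDeficiencyError("design matrix is rank deficient")
    XtX_inv = np.linalg.inv(XtX)
    B = XtX_inv @ X.T @ Y
    resid = Y - X @ B
    E = resid.T @ resid
    df_error = n_obs - k

    results = []
    col = 1
    for effect, Xe in blocks.items():
        q = Xe.shape[1]
        L = np.zeros((q, k))
        L[:, col:col + q] = np.eye(q)
        col += q
        LB = L @ B
        H = LB.T @ np.linalg.inv(L @ XtX_inv @ L.T) @ LB
        results.append(_pillai_from_he(effect, H, E, p, q, df_error, names))
    return results


@dataclass(frozen=True)
class BoxMResult:
    M: float
    chi2: float
    df: int
    p: float


def box_m(data, groups) -> BoxMResult:
    """Box's M test for homogeneity of covariance matrices, with the
    standard chi-squared approximation."""
    Y, _ = _as_matrix(data)
    labels = np.asarray(groups)
    levels = list(pd.unique(labels))
    g = len(levels)
    n_obs, p = Y.shape
    pooled = np.zeros((p, p))
    logdets, dfs = [], []
    for lev in levels:
        sub = Y[labels == lev]
        ni = len(sub)
        if ni <= p:
            raise ValueError(f"group {lev!r} needs more than p={p} cases")
        S = np.cov(sub, rowvar=False, ddof=1).reshape(p, p)
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            raise RankDeficiencyError(f"singular covariance in group {lev!r}")
        logdets.append(logdet)
        dfs.append(ni - 1)
        pooled += (ni - 1) * S
    df_pool = n_obs - g
    pooled /= df_pool
    sign, logdet_pool = np.linalg.slogdet(pooled)
    if sign <= 0:
        raise RankDeficiencyError("singular pooled covariance")
    M = df_pool * logdet_pool - sum(d * ld for d, ld in zip(dfs, logdets))
    c1 = ((sum(1.0 / d for d in dfs) - 1.0 / df_pool)
          * (2 * p * p + 3 * p - 1) / (6.0 * (p + 1) * (g - 1)))
    chi2 = M * (1 - c1)
    df = p * (p + 1) * (g - 1) // 2
    return BoxMResult(M=float(M), chi2=float(chi2), df=int(df),
                      p=float(chi2_dist.sf(chi2, df)))


@dataclass(frozen=True)
class ScreenResult:
    """Pairwise Pearson correlations with multicollinearity flags."""

    corr: pd.DataFrame
    flags: list            # (var_i, var_j, r) with |r| >= threshold
    undefined: list        # zero-variance variables (r undefined)
    threshold: float


def pearson_screen(data, threshold: float = 0.9) -> ScreenResult:
    """Pairwise Pearson correlation matrix; flags |r| >= threshold.

    Zero-variance columns yield undefined correlations which are reported
    in ``undefined`` rather than raising.
    """
    if isinstance(data, pd.DataFrame):
        df = data.astype(float)
    else:
        arr = np.asarray(data, dtype=float)
        df = pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])
    if len(df) < 3:
        raise ValueError("need at least 3 rows")
    undefined = [c for c in df.columns if df[c].std(ddof=1) == 0]
    corr = df.corr(method="pearson")
    flags = []
    cols = list(df.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = corr.iloc[i, j]
            if np.isfinite(r) and abs(r) >= threshold:
                flags.append((cols[i], cols[j], float(r)))
    return ScreenResult(corr=corr, flags=flags, undefined=undefined,
                        threshold=threshold)
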
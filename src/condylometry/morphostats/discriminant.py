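"""Stepwise linear discriminant analysis driven by Wilks' lambda.

Variable selection is forward with backward removal: at each step the
candidate minimizing the overall Wilks' Λ enters if its partial F exceeds
``f_enter``; any included variable whose partial F falls to ``f_remove``
or below leaves. The partial F of variable v relative to an included set
S is

    F = ((n − g − |S|) / (g − 1)) · (Λ(S)/Λ(S ∪ {v}) − 1),

with ``Λ(S) = det(W_S)/det(T_S)`` (within vs total cross-products).

On the selected set the canonical discriminant functions solve the
generalized eigenproblem ``B v = λ W v`` (between vs within); each
function's squared canonical correlation is ``λ/(1+λ)``, the overall
Λ is ``Π 1/(1+λ_i)``, and Bartlett's sequential chi-squared tests

    χ²_k = (n − 1 − (p + g)/2) · Σ_{i>k} ln(1 + λ_i),
    df_k = (p − k)(g − 1 − k)

assess the functions remaining after removing the first k. Structure
coefficients are pooled within-group correlations between each candidate
variable and the function scores. Classification uses Fisher's linear
classification functions with priors proportional to group sizes by
default (``priors="equal"`` for flat priors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.stats import chi2 as chi2_dist

from ..errors import RankDeficiencyError


@dataclass
class DiscriminantModel:
    """Fitted stepwise LDA."""

    variables: List[str]                 # selected, in entry order
    groups: List                         # group labels, fixed order
    priors: np.ndarray
    eigenvalues: np.ndarray
    canonical_r2: np.ndarray
    wilks_lambda: float
    residual_tests: pd.DataFrame         # k, lambda, chi2, df, p
    structure: pd.DataFrame              # candidate vars × functions
    coefficients: np.ndarray             # p_sel × n_func, within-normalized
    class_coef: np.ndarray               # g × p_sel Fisher coefficients
    class_const: np.ndarray              # g intercepts (incl. log prior)
    explained_variance: np.ndarray
    means: pd.DataFrame                  # group means of selected variables
    history: list = field(default_factory=list)
    diagnostic: Optional[str] = None
    grand_mean: Optional[np.ndarray] = None

    @property
    def n_functions(self) -> int:
        return len(self.eigenvalues)

    def decision_scores(self, data) -> np.ndarray:
        X = _columns(data, self.variables)
        return X @ self.class_coef.T + self.class_const

    def predict(self, data) -> np.ndarray:
        if not self.variables:
            raise ValueError("empty model cannot predict")
        scores = self.decision_scores(data)
        return np.asarray(self.groups, object)[np.argmax(scores, axis=1)]

    def transform(self, data) -> np.ndarray:
        """Canonical discriminant scores (centered at the grand mean)."""
        if not self.variables:
            raise ValueError("empty model cannot transform")
        X = _columns(data, self.variables)
        return (X - self.grand_mean) @ self.coefficients


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data.astype(float)
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])


def _columns(data, names) -> np.ndarray:
    df = _as_frame(data)
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise KeyError(f"missing variables: {missing}")
    return df[names].to_numpy()


def _sscp(Y: np.ndarray, labels: np.ndarray, levels) -> tuple:
    """Within-group (W) and total (T) cross-product matrices."""
    grand = Y.mean(axis=0)
    Tc = Y - grand
    T = Tc.T @ Tc
    W = np.zeros_like(T)
    for lev in levels:
        sub = Y[labels == lev]
        c = sub - sub.mean(axis=0)
        W += c.T @ c
    return W, T


def _wilks(W: np.ndarray, T: np.ndarray, idx: Sequence[int]) -> float:
    if not idx:
        return 1.0
    ii = np.ix_(idx, idx)
    sw, ldw = np.linalg.slogdet(W[ii])
    st, ldt = np.linalg.slogdet(T[ii])
    if sw <= 0 or st <= 0:
        raise RankDeficiencyError("singular within or total matrix during "
                                  "stepwise selection")
    return float(np.exp(ldw - ldt))


def partial_f(W, T, included, candidate, n, g) -> float:
    """Partial F of ``candidate`` given ``included`` (entry/removal F)."""
    lam_old = _wilks(W, T, included)
    lam_new = _wilks(W, T, included + [candidate])
    p_in = len(included)
    if lam_new <= 0:
        return np.inf
    return (n - g - p_in) / (g - 1) * (lam_old / lam_new - 1.0)


def stepwise_lda(data, groups, f_enter: float = 3.84, f_remove: float = 2.71,
                 priors: str = "proportional") -> DiscriminantModel:
    """Fit the stepwise Wilks'-Λ discriminant model.

    Returns an empty model (no variables, ``diagnostic`` set) when no
    candidate reaches ``f_enter``.
    """
    if f_remove >= f_enter:
        raise ValueError("f_remove must be below f_enter")
    df = _as_frame(data)
    labels = np.asarray(groups)
    if len(labels) != len(df):
        raise ValueError("groups length mismatch")
    levels = list(pd.unique(labels))
    g = len(levels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    names = list(df.columns)
    Y = df.to_numpy()
    n, p = Y.shape
    if n <= p + g:
        raise ValueError("too few observations")
    W, T = _sscp(Y, labels, levels)

    included: List[int] = []
    history = []
    for _ in range(2 * p * p + 4):
        # removal phase
        while included:
            fs = {v: partial_f(W, T, [u for u in included if u != v], v, n, g)
                  for v in included}
            worst = min(fs, key=fs.get)
            if fs[worst] <= f_remove:
                included.remove(worst)
                history.append(("remove", names[worst], fs[worst]))
            else:
                break
        # entry phase
        candidates = [v for v in range(p) if v not in included]
        best, best_f, best_lam = None, -np.inf, np.inf
        for v in candidates:
            try:
                lam = _wilks(W, T, included + [v])
            except RankDeficiencyError:
                continue  # tolerance: skip collinear candidates
            fv = partial_f(W, T, included, v, n, g)
            if lam < best_lam - 1e-12:
                best, best_f, best_lam = v, fv, lam
        if best is None or best_f < f_enter:
            break
        included.append(best)
        history.append(("enter", names[best], best_f))
    else:  # pragma: no cover - cycling guard
        raise RuntimeError("stepwise selection did not converge")

    group_sizes = np.array([(labels == lev).sum() for lev in levels], float)
    if priors == "proportional":
        pri = group_sizes / n
    elif priors == "equal":
        pri = np.full(g, 1.0 / g)
    else:
        raise ValueError("priors must be 'proportional' or 'equal'")

    if not included:
        return DiscriminantModel(
            variables=[], groups=levels, priors=pri,
            eigenvalues=np.array([]), canonical_r2=np.array([]),
            wilks_lambda=1.0,
            residual_tests=pd.DataFrame(
                columns=["k", "wilks", "chi2", "df", "p"]),
            structure=pd.DataFrame(index=names),
            coefficients=np.zeros((0, 0)), class_coef=np.zeros((g, 0)),
            class_const=np.log(pri), explained_variance=np.array([]),
            means=pd.DataFrame(), history=history,
            diagnostic="no variable reached the entry threshold "
                       f"(f_enter={f_enter})")

    sel = list(included)
    sel_names = [names[v] for v in sel]
    Ys = Y[:, sel]
    p_sel = len(sel)
    Ws = W[np.ix_(sel, sel)]
    Ts = T[np.ix_(sel, sel)]
    Bs = Ts - Ws

    n_func = min(p_sel, g - 1)
    # generalized symmetric eigenproblem B v = lambda W v
    try:
        eigvals, eigvecs = eigh(Bs, Ws)
    except np.linalg.LinAlgError as exc:
        raise RankDeficiencyError("singular within-group matrix") from exc
    order = np.argsort(eigvals)[::-1][:n_func]
    lam = np.clip(eigvals[order], 0.0, None)
    V = eigvecs[:, order]
    # scale so pooled within-group variance of scores is one
    V = V * np.sqrt(n - g)

    canonical_r2 = lam / (1 + lam)
    wilks = float(np.prod(1.0 / (1.0 + lam)))
    bart = []
    factor = n - 1 - (p_sel + g) / 2.0
    for k in range(n_func):
        lam_k = float(np.prod(1.0 / (1.0 + lam[k:])))
        chi2 = factor * np.sum(np.log1p(lam[k:]))
        dfk = (p_sel - k) * (g - 1 - k)
        bart.append((k, lam_k, float(chi2), int(dfk),
                     float(chi2_dist.sf(chi2, dfk))))
    residual_tests = pd.DataFrame(bart,
                                  columns=["k", "wilks", "chi2", "df", "p"])

    # structure coefficients: pooled within-group correlations of every
    # candidate variable with the function scores
    grand = Y.mean(axis=0)
    Yw = np.empty_like(Y)
    for lev in levels:
        mask = labels == lev
        Yw[mask] = Y[mask] - Y[mask].mean(axis=0)
    scores_w = Yw[:, sel] @ V
    num = Yw.T @ scores_w
    denom = np.sqrt(np.outer((Yw ** 2).sum(axis=0),
                             (scores_w ** 2).sum(axis=0)))
    with np.errstate(invalid="ignore", divide="ignore"):
        structure = pd.DataFrame(
            num / denom, index=names,
            columns=[f"function_{i + 1}" for i in range(n_func)])

    # Fisher linear classification functions
    Sp = Ws / (n - g)
    Sp_inv = np.linalg.inv(Sp)
    mu = np.vstack([Ys[labels == lev].mean(axis=0) for lev in levels])
    class_coef = mu @ Sp_inv
    class_const = -0.5 * np.einsum("ij,ij->i", class_coef, mu) + np.log(pri)

    explained = lam / lam.sum() if lam.sum() > 0 else lam
    model = DiscriminantModel(
        variables=sel_names, groups=levels, priors=pri,
        eigenvalues=lam, canonical_r2=canonical_r2, wilks_lambda=wilks,
        residual_tests=residual_tests, structure=structure,
        coefficients=V, class_coef=class_coef, class_const=class_const,
        explained_variance=explained,
        means=pd.DataFrame(mu, index=levels, columns=sel_names),
        history=history, grand_mean=grand[sel])
    return model


@dataclass(frozen=True)
class ClassificationTable:
    """Resubstitution confusion counts, row percentages, overall percent."""

    counts: pd.DataFrame
    row_percent: pd.DataFrame
    overall_percent: float


def lda_classification_table(model: DiscriminantModel, data,
                             groups) -> ClassificationTable:
    """Classify the training cases and tabulate original × predicted."""
    labels = np.asarray(groups)
    unseen = set(pd.unique(labels)) - set(model.groups)
    if unseen:
        raise ValueError(f"unseen group labels: {sorted(map(str, unseen))}")
    pred = model.predict(data)
    counts = pd.crosstab(pd.Series(labels, name="original"),
                         pd.Series(pred, name="predicted"))
    counts = counts.reindex(index=model.groups, columns=model.groups,
                            fill_value=0)
    row_pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    overall = 100.0 * np.trace(counts.to_numpy()) / counts.to_numpy().sum()
    return ClassificationTable(counts=counts, row_percent=row_pct,
                               overall_percent=float(overall))
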
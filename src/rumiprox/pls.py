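"""Partial least squares regression with VIP-based sequential gene selection.

The PLS model is fitted by NIPALS with response deflation on autoscaled
(centered, unit-variance) X and y. For a univariate response the weight
vector of each factor is the correlation direction of the deflated
predictors with the deflated response; scores are mutually orthogonal and
per-factor variance accounting is reported for both blocks ("model
effects" = X, "dependent variable" = y), current and cumulative.

Variable importance in projection (VIP) summarizes each predictor's
contribution across factors; mean squared VIP is exactly 1, so VIP ~ 1 is
the natural "average importance" reference. The number of factors is
chosen by leave-one-out cross-validation (minimum PRESS, with centering
and scaling recomputed inside every fold).

The two-stage selection procedure: (1) iteratively refit PLS (factors by
LOO-CV) and drop the genes with the lowest VIP; (2) re-evaluate every
candidate set with a fixed three-factor model and keep the set with the
highest explained response variance. Class dummies ride along in the X
block but are never ranked or dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class PLSFit:
    """Fitted NIPALS PLS model on autoscaled data (univariate response)."""

    n_factors: int
    columns: list[str]
    weights: np.ndarray  # p x A, unit columns
    scores: np.ndarray  # n x A
    x_loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # A
    coef_scaled: np.ndarray  # p, for autoscaled X and y
    coef: np.ndarray  # p, input scale
    intercept: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    x_variance_current: np.ndarray  # percent per factor
    y_variance_current: np.ndarray

    @property
    def x_variance_total(self) -> np.ndarray:
        return np.cumsum(self.x_variance_current)

    @property
    def y_variance_total(self) -> np.ndarray:
        return np.cumsum(self.y_variance_current)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.coef


def fit_pls(X, y, n_factors: int, columns: list[str] | None = None) -> PLSFit:
    """Fit a univariate-response PLS model by NIPALS with y deflation.

    X and y are autoscaled internally. Per-factor percent X variance is
    ``100 * |t_a p_a'|^2_F / |X0|^2_F`` and percent y variance comes from
    successive deflation of the response.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if columns is None:
        columns = [f"x{j}" for j in range(p)]
    if len(y) != n:
        raise ValueError("X and y length mismatch")
    if n < 3 or p < 1:
        raise ValueError("need n >= 3 and p >= 1")
    if not (1 <= n_factors <= min(n - 1, p)):
        raise ValueError(f"n_factors {n_factors} out of range for {n}x{p}")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    x_mean, x_scale = X.mean(axis=0), X.std(axis=0, ddof=1)
    if (x_scale == 0).any():
        bad = [columns[j] for j in np.flatnonzero(x_scale == 0)]
        raise ValueError(f"zero-variance columns: {bad[:5]}")
    y_mean, y_scale = y.mean(), y.std(ddof=1)
    if y_scale == 0:
        raise ValueError("zero-variance response")
    Xc = (X - x_mean) / x_scale
    yc = (y - y_mean) / y_scale
    ssx0 = (Xc**2).sum()
    ssy0 = (yc**2).sum()

    W = np.zeros((p, n_factors))
    T = np.zeros((n, n_factors))
    P = np.zeros((p, n_factors))
    q = np.zeros(n_factors)
    xvar = np.zeros(n_factors)
    yvar = np.zeros(n_factors)
    Xa, ya = Xc.copy(), yc.copy()
    for a in range(n_factors):
        w = Xa.T @ ya
        nw = np.linalg.norm(w)
        if nw < 1e-300:
            logger.warning("NIPALS: degenerate factor %d, stopping early", a + 1)
            n_factors = a
            W, T, P, q = W[:, :a], T[:, :a], P[:, :a], q[:a]
            xvar, yvar = xvar[:a], yvar[:a]
            break
        w = w / nw
        # sign convention: largest-magnitude weight positive
        j = np.argmax(np.abs(w))
        if w[j] < 0:
            w = -w
        t = Xa @ w
        tt = t @ t
        pvec = Xa.T @ t / tt
        qa = ya @ t / tt
        Xa = Xa - np.outer(t, pvec)
        ya = ya - qa * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, pvec, qa
        xvar[a] = 100.0 * tt * (pvec @ pvec) / ssx0
        yvar[a] = 100.0 * qa**2 * tt / ssy0
    if n_factors == 0:
        raise ValueError("no usable PLS factor (response orthogonal to X)")

    # b = W (P'W)^-1 q in autoscaled space
    bs = W @ np.linalg.solve(P.T @ W, q)
    coef = bs * y_scale / x_scale
    intercept = float(y_mean - x_mean @ coef)
    return PLSFit(
        n_factors=n_factors, columns=list(columns), weights=W, scores=T,
        x_loadings=P, y_loadings=q, coef_scaled=bs, coef=coef,
        intercept=intercept, x_mean=x_mean, x_scale=x_scale,
        y_mean=float(y_mean), y_scale=float(y_scale),
        x_variance_current=xvar, y_variance_current=yvar)


def compute_vip(fit: PLSFit) -> pd.Series:
    """VIP_j = sqrt(p * sum_a SSY_a (w_ja/|w_a|)^2 / sum_a SSY_a).

    SSY_a is the response variance explained by factor a; weight columns
    are already unit norm. Satisfies sum(VIP^2) = p exactly.
    """
    p = fit.weights.shape[0]
    ssy = fit.y_variance_current
    denom = ssy.sum()
    if denom <= 0:
        return pd.Series(np.ones(p), index=fit.columns, name="VIP")
    vip = np.sqrt(p * (fit.weights**2 @ ssy) / denom)
    return pd.Series(vip, index=fit.columns, name="VIP")


@dataclass
class CVReport:
    press: pd.Series  # indexed by number of factors
    q2: pd.Series
    chosen: int
    root_mean_press: pd.Series


def loo_select_factors(X, y, max_factors: int = 10,
                       columns: list[str] | None = None) -> CVReport:
    """Choose the number of PLS factors by leave-one-out cross-validation.

    For every candidate A each animal is held out in turn, the model is
    refitted (autoscaling recomputed inside the fold; zero-variance
    columns dropped within the fold), and the held-out response is
    predicted. The chosen A minimizes PRESS. Q2 = 1 - PRESS/SS_tot.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 4:
        raise ValueError("LOO factor selection needs n >= 4")
    a_max = min(max_factors, n - 2, p)
    preds = np.full((n, a_max), np.nan)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xi, yi = X[mask], y[mask]
        keep = Xi.std(axis=0) > 0
        if not keep.all():
            logger.info("LOO fold %d: dropping %d zero-variance columns",
                        i, int((~keep).sum()))
        a_fold = min(a_max, int(keep.sum()))
        fit = fit_pls(Xi[:, keep], yi, a_fold)
        # predictions for every factor count from one fit
        Xc = (X[i, keep] - fit.x_mean) / fit.x_scale
        xa = Xc.copy()
        yhat = fit.y_mean
        for a in range(a_max):
            if a < fit.n_factors:
                t = xa @ fit.weights[:, a]
                yhat = yhat + fit.y_scale * fit.y_loadings[a] * t
                xa = xa - t * fit.x_loadings[:, a]
            preds[i, a] = yhat
    ss_tot = ((y - y.mean())**2).sum()
    idx = pd.RangeIndex(1, a_max + 1, name="n_factors")
    press = pd.Series(((preds - y[:, None])**2).sum(axis=0), index=idx, name="PRESS")
    q2 = pd.Series(1 - press / ss_tot, index=idx, name="Q2")
    chosen = int(press.idxmin())
    return CVReport(press=press, q2=q2, chosen=chosen,
                    root_mean_press=np.sqrt(press / n).rename("rootPRESS"))


@dataclass
class GeneSelection:
    """Result of the sequential VIP elimination for one trait."""

    trait: str
    table: pd.DataFrame  # KO, pls_estimate (autoscaled coef), vip, sign
    explained_y_with_class: float  # percent, A = eval factors
    explained_y_without_class: float
    explained_x_with_class: float
    variance_table: pd.DataFrame  # per-factor current/total, both blocks
    candidate_sizes: list[int] = field(default_factory=list)
    cv: CVReport | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.table["ko"])


def variance_table(fit: PLSFit) -> pd.DataFrame:
    """Per-factor percent-variance table (current and cumulative totals)."""
    return pd.DataFrame({
        "factor": np.arange(1, fit.n_factors + 1),
        "model_effects_current": fit.x_variance_current,
        "model_effects_total": fit.x_variance_total,
        "dependent_current": fit.y_variance_current,
        "dependent_total": fit.y_variance_total,
    })


def cumulative_totals(currents) -> np.ndarray:
    """Cumulative 'Total' column from per-factor 'Current' values."""
    return np.cumsum(np.asarray(currents, dtype=float))


def class_dummies(class6: pd.Series) -> pd.DataFrame:
    """Reference-coded dummy columns for the combined class factor."""
    d = pd.get_dummies(pd.Series(class6).astype(str), prefix="class",
                       drop_first=True, dtype=float)
    return d


def sequential_select(
    gene_matrix: pd.DataFrame,
    y,
    trait: str,
    class6: pd.Series | None = None,
    vip_threshold: float = 1.0,
    max_drop_frac: float = 0.2,
    eval_factors: int = 3,
    max_factors_cv: int = 10,
    rsq_tolerance: float = 3.0,
    criterion: str = "combined",
    max_iter: int = 100,
) -> GeneSelection:
    """Two-stage sequential PLS gene selection for one trait.

    Stage 1: loop { choose factors by LOO-CV, fit, drop genes with
    VIP < ``vip_threshold`` but at most the bottom ``max_drop_frac``
    fraction per iteration }, recording every candidate set, until no
    gene falls below the threshold or fewer than 2 genes remain. Because
    mean squared VIP is identically 1, the default threshold of 1.0
    removes the below-average-importance genes each round and traces the
    candidate trajectory all the way down.

    Stage 2: refit every candidate set with ``eval_factors`` factors
    (class dummies included) and score it by the explained variance of
    both blocks at once (``criterion="combined"``, the product of the
    X-block and response percentages — noise genes depress the X block,
    so coherent small sets win) or of the response alone
    (``criterion="dependent"``). The smallest set scoring within
    ``rsq_tolerance`` points of the best is returned (the parsimony
    rule: nearly-equivalent smaller sets are preferred). The chosen set
    is also refitted without the class dummies to report the
    no-fixed-effect explained variance.
    """
    if criterion not in ("combined", "dependent"):
        raise ValueError(f"unknown criterion {criterion!r}")
    y = np.asarray(y, dtype=float).ravel()
    dummies = class_dummies(class6) if class6 is not None else pd.DataFrame(index=gene_matrix.index)
    current = list(gene_matrix.columns)
    if len(current) < 2:
        raise ValueError("sequential selection needs at least 2 genes")
    candidates: list[list[str]] = [list(current)]
    for _ in range(max_iter):
        X = np.column_stack([gene_matrix[current].to_numpy(float),
                             dummies.to_numpy(float)]) if len(dummies.columns) else \
            gene_matrix[current].to_numpy(float)
        cols = current + list(dummies.columns)
        cv = loo_select_factors(X, y, max_factors=max_factors_cv, columns=cols)
        fit = fit_pls(X, y, cv.chosen, columns=cols)
        vip = compute_vip(fit).iloc[: len(current)]  # gene columns only
        below = vip[vip < vip_threshold]
        if below.empty:
            break
        n_drop = max(1, min(len(below), int(np.floor(max_drop_frac * len(current)))))
        drop = set(below.nsmallest(n_drop).index)
        nxt = [g for g in current if g not in drop]
        if len(nxt) < 2:
            logger.info("%s: selection would collapse below 2 genes; stopping", trait)
            break
        current = nxt
        candidates.append(list(current))

    # stage 2: evaluate candidate sets at the fixed factor count
    evals = []
    for genes in candidates:
        X = np.column_stack([gene_matrix[genes].to_numpy(float),
                             dummies.to_numpy(float)]) if len(dummies.columns) else \
            gene_matrix[genes].to_numpy(float)
        a = min(eval_factors, len(genes) + len(dummies.columns), len(y) - 1)
        fit = fit_pls(X, y, a, columns=genes + list(dummies.columns))
        ry = float(fit.y_variance_total[-1])
        rx = float(fit.x_variance_total[-1])
        score = ry * rx / 100.0 if criterion == "combined" else ry
        evals.append((genes, fit, score))
    s_max = max(e[2] for e in evals)
    eligible = [e for e in evals if e[2] >= s_max - rsq_tolerance]
    genes, fit, _ = min(eligible, key=lambda e: len(e[0]))
    r_with = float(fit.y_variance_total[-1])

    if len(dummies.columns):
        a = min(eval_factors, len(genes), len(y) - 1)
        fit_nc = fit_pls(gene_matrix[genes].to_numpy(float), y, a, columns=genes)
        r_without = float(fit_nc.y_variance_total[-1])
    else:
        r_without = r_with

    vip = compute_vip(fit)
    table = pd.DataFrame({
        "ko": genes,
        "pls_estimate": fit.coef_scaled[: len(genes)],
        "vip": vip.iloc[: len(genes)].to_numpy(),
    })
    table["sign"] = np.sign(table["pls_estimate"]).astype(int)
    table = table.reindex(table["vip"].abs().sort_values(ascending=False).index)
    table = table.reset_index(drop=True)
    return GeneSelection(
        trait=trait, table=table,
        explained_y_with_class=r_with,
        explained_y_without_class=r_without,
        explained_x_with_class=float(fit.x_variance_total[-1]),
        variance_table=variance_table(fit),
        candidate_sizes=[len(c) for c in candidates],
        cv=None)
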
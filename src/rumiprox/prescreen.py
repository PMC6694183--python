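"""Per-gene fixed-effect linear models screening genes before PLS.

For every gene, the relative abundance is the response in a linear model
with the combined six-level breed x diet x year class as a fixed effect
plus the trait term: a two-level high/low group factor for FCR, or the
continuous trait value for ADG, RFI and DFI. The trait term's partial
F-test p-value (equivalently the squared t-test for these 1-df terms)
decides retention: genes with p >= alpha (default 0.1) are excluded from
the PLS stage. No multiple-testing correction is applied at this stage —
the screen is deliberately liberal, existing only to drop genes showing
no association at all.

All genes share one design matrix, so the screen is computed with two
QR projections (full and reduced model) applied to the whole abundance
matrix at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import AbundanceMatrix
from .pls import class_dummies

logger = logging.getLogger(__name__)


@dataclass
class PrescreenResult:
    trait: str
    alpha: float
    encoding: str  # "group" or "continuous"
    table: pd.DataFrame  # ko, estimate, statistic, p, retained

    @property
    def retained(self) -> list[str]:
        return list(self.table.loc[self.table["retained"], "ko"])


def _design(class6: pd.Series, trait_term: np.ndarray | None) -> np.ndarray:
    d = class_dummies(class6).to_numpy(float)
    cols = [np.ones(len(class6)), d]
    if trait_term is not None:
        cols.append(trait_term.reshape(-1, 1))
    return np.hstack([c if c.ndim == 2 else c.reshape(-1, 1) for c in cols])


def prescreen_gene(abundance, class6, trait_term) -> tuple[float, float]:
    """Partial F-test of the trait term for a single gene.

    Provided for clarity and testing; :func:`prescreen_all` is the
    vectorized path. Returns ``(p_value, estimate)``.
    """
    res = prescreen_all_values(
        np.asarray(abundance, float).reshape(-1, 1), pd.Series(class6),
        np.asarray(trait_term, float))
    return float(res["p"][0]), float(res["estimate"][0])


def prescreen_all_values(Y: np.ndarray, class6: pd.Series,
                         trait_term: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized trait-term partial F-tests for all gene columns of Y."""
    n, p = Y.shape
    X_full = _design(class6, trait_term)
    X_red = _design(class6, None)
    rank_full = np.linalg.matrix_rank(X_full)
    rank_red = np.linalg.matrix_rank(X_red)
    if rank_full == rank_red:
        # trait term aliased with the class factor: nothing is estimable
        logger.warning("trait term aliased with class factor; all genes flagged")
        return {"p": np.ones(p), "estimate": np.zeros(p),
                "statistic": np.zeros(p), "estimable": np.zeros(p, bool)}
    if n <= rank_full:
        raise ValueError("not enough animals for the prescreen model")

    def rss(X: np.ndarray) -> np.ndarray:
        Q, _ = np.linalg.qr(X)
        resid = Y - Q @ (Q.T @ Y)
        return (resid**2).sum(axis=0)

    rss_full, rss_red = rss(X_full), rss(X_red)
    df_num = rank_full - rank_red
    df_den = n - rank_full
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (rss_red - rss_full) / df_num / (rss_full / df_den)
    beta, *_ = np.linalg.lstsq(X_full, Y, rcond=None)
    estimate = beta[-1]
    degenerate = Y.std(axis=0) == 0
    F = np.where(np.isfinite(F) & ~degenerate, F, 0.0)
    pvals = stats.f.sf(F, df_num, df_den)
    pvals[degenerate] = 1.0
    estimate[degenerate] = 0.0
    return {"p": pvals, "estimate": estimate, "statistic": F,
            "estimable": ~degenerate}


def _reverse_screen(Y: np.ndarray, class6: pd.Series,
                    trait: np.ndarray) -> dict[str, np.ndarray]:
    """Reversed direction: trait ~ class + gene, one model per gene.

    After projecting out the class factor from both sides, the partial F
    of each gene is a function of the residual correlation, computed for
    all genes at once.
    """
    n, p = Y.shape
    X_red = _design(class6, None)
    Q, _ = np.linalg.qr(X_red)
    rank_red = np.linalg.matrix_rank(X_red)
    rt = trait - Q @ (Q.T @ trait)
    rg = Y - Q @ (Q.T @ Y)
    sg = np.sqrt((rg**2).sum(axis=0))
    st = np.sqrt((rt**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (rg.T @ rt) / (sg * st)
        slope = (rg.T @ rt) / sg**2
    df_den = n - rank_red - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        F = df_den * r**2 / (1 - r**2)
    degenerate = ~np.isfinite(F) | (sg == 0)
    F = np.where(degenerate, 0.0, F)
    pvals = stats.f.sf(F, 1, df_den)
    pvals[degenerate] = 1.0
    return {"p": pvals, "estimate": np.where(degenerate, 0.0, slope),
            "statistic": F, "estimable": ~degenerate}


def prescreen_all(
    matrix: AbundanceMatrix,
    phenotypes: pd.DataFrame,
    trait: str,
    class6: pd.Series | None = None,
    alpha: float = 0.1,
    group_labels: pd.Series | None = None,
    transform: str = "none",
    reverse: bool = False,
) -> PrescreenResult:
    """Screen every gene against one trait.

    For FCR the trait term is the 2-level high/low group factor (coded
    0/1); for the other traits it is the continuous trait value. Animal
    ids of the abundance matrix and phenotype table must match.

    ``transform="log10"`` screens log10(abundance + half of the smallest
    nonzero value) instead of the raw fractions. ``reverse=True`` flips
    the regression direction (trait as response, gene plus class as
    predictors); for 1-df trait terms the default direction's p-value is
    identical, so this only matters for the group screen's estimates.
    """
    ids_m = list(matrix.animals)
    ids_p = list(phenotypes["animal_id"])
    if set(ids_m) != set(ids_p):
        raise ValueError(
            f"animal id mismatch; only in abundance: {sorted(set(ids_m) - set(ids_p))[:5]}, "
            f"only in phenotypes: {sorted(set(ids_p) - set(ids_m))[:5]}")
    phen = phenotypes.set_index("animal_id").loc[ids_m]
    if class6 is None:
        class6 = (phen["breed"].astype(str) + "|" + phen["diet"].astype(str)
                  + "|" + phen["year"].astype(str))
    else:
        class6 = pd.Series(class6).set_axis(ids_m)

    if trait == "FCR":
        encoding = "group"
        if group_labels is not None:
            lab = pd.Series(group_labels).set_axis(ids_m)
        elif f"{trait}_group" in phen.columns:
            lab = phen[f"{trait}_group"]
        else:
            from .phenotypes import median_split
            lab = pd.Series(median_split(phen[trait].to_numpy(float),
                                         class6.to_numpy()), index=ids_m)
        trait_term = (lab == "high").to_numpy(float)
    else:
        encoding = "continuous"
        trait_term = phen[trait].to_numpy(float)

    Y = matrix.values.to_numpy(float)
    if transform == "log10":
        nonzero = Y[Y > 0]
        offset = 0.5 * (nonzero.min() if len(nonzero) else 1.0)
        Y = np.log10(Y + offset)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    if reverse:
        res = _reverse_screen(Y, class6, trait_term)
    else:
        res = prescreen_all_values(Y, class6, trait_term)
    table = pd.DataFrame({
        "ko": matrix.genes,
        "estimate": res["estimate"],
        "statistic": res["statistic"],
        "p": res["p"],
    })
    table["retained"] = table["p"] < alpha
    logger.info("prescreen %s: %d / %d genes retained at alpha=%g",
                trait, int(table["retained"].sum()), len(table), alpha)
    return PrescreenResult(trait=trait, alpha=alpha, encoding=encoding, table=table)
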
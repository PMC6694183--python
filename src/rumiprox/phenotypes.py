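"""Derivation of cattle feed-efficiency traits from per-animal records.

The four performance traits used throughout the pipeline are

* **DFI** — daily feed intake, the mean daily dry-matter intake (kg/day);
* **ADG** — average daily gain (kg/day), the slope of body weight regressed
  on test day;
* **FCR** — feed conversion ratio, DFI / ADG (kg intake per kg gain;
  lower = more efficient);
* **RFI** — residual feed intake, the residual of DFI regressed on ADG,
  metabolic mid-test body weight (MBW = mid-test BW^0.75) and rib fat
  depth (kg/day; mean zero by construction, lower = more efficient).

Animals are grouped by a combined six-level class of breed, diet and trial
year, and split into high/low groups per trait by a stratified median rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

TRAITS = ("FCR", "ADG", "RFI", "DFI")

PHENOTYPE_COLUMNS = [
    "animal_id", "breed", "diet", "year", "additive",
    "DFI", "ADG", "FCR", "RFI", "MBW", "fat_depth",
]


class CollinearityError(ValueError):
    """Raised when a regression design is rank deficient."""


@dataclass
class AnimalRecord:
    """Raw per-animal inputs from which traits are derived."""

    animal_id: str
    breed: str
    diet: str
    year: str
    additive: str = "control"
    bw_series: list[tuple[float, float]] = field(default_factory=list)  # (day, kg)
    dmi_daily: list[float] = field(default_factory=list)  # kg/day
    fat_depth: float = float("nan")  # mm at 12th/13th rib


def derive_adg(bw_series: Sequence[tuple[float, float]]) -> tuple[float, float, float]:
    """Regress body weight on test day to obtain growth summaries.

    Parameters
    ----------
    bw_series
        Sequence of ``(day, body_weight_kg)`` pairs with at least two
        distinct days.

    Returns
    -------
    (adg, mid_bw, mbw)
        OLS slope in kg/day, the fitted weight at the midpoint of the
        date range, and the metabolic weight ``mid_bw ** 0.75``.
    """
    arr = np.asarray(bw_series, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("bw_series needs at least two (day, BW) points")
    days, bw = arr[:, 0], arr[:, 1]
    if np.ptp(days) == 0:
        raise ValueError("all body-weight dates identical; ADG slope undefined")
    slope, intercept = np.polyfit(days, bw, 1)
    mid_day = 0.5 * (days.min() + days.max())
    mid_bw = intercept + slope * mid_day
    return float(slope), float(mid_bw), float(mid_bw**0.75)


def derive_fcr(dfi: float, adg: float) -> float:
    """Feed conversion ratio: DFI divided by ADG. Requires positive gain."""
    if adg <= 0:
        raise ValueError(f"non-positive ADG ({adg}); FCR undefined, exclude animal")
    return dfi / adg


def derive_rfi(table: pd.DataFrame, extra_covariates: pd.DataFrame | None = None) -> np.ndarray:
    """Residual feed intake for every animal.

    DFI is regressed by OLS on ADG, MBW and fat depth (optionally plus
    extra covariate columns, e.g. class dummies); the residual, in input
    order, is RFI. Residuals have mean zero and are orthogonal to every
    predictor by construction.
    """
    required = {"DFI", "ADG", "MBW", "fat_depth"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"derive_rfi missing columns: {sorted(missing)}")
    n = len(table)
    if n < 5:
        raise ValueError("derive_rfi needs at least 5 animals")
    cols = [np.ones(n), table["ADG"].to_numpy(float),
            table["MBW"].to_numpy(float), table["fat_depth"].to_numpy(float)]
    names = ["intercept", "ADG", "MBW", "fat_depth"]
    if extra_covariates is not None:
        for c in extra_covariates.columns:
            cols.append(extra_covariates[c].to_numpy(float))
            names.append(str(c))
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                bad.append(names[j])
            r = rj
        raise CollinearityError(f"RFI design rank deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, table["DFI"].to_numpy(float), rcond=None)
    return table["DFI"].to_numpy(float) - X @ beta


def median_split(values: Sequence[float], strata: Sequence) -> np.ndarray:
    """Stratified high/low split around the within-stratum median.

    Within each stratum the animals whose value exceeds the stratum median
    are labelled ``"high"`` and the rest ``"low"``; an animal exactly at
    the median goes to ``"low"`` (fixed tie rule). Group sizes within a
    stratum differ by at most one.
    """
    values = np.asarray(values, dtype=float)
    strata = np.asarray(strata)
    if len(values) != len(strata):
        raise ValueError("values and strata length mismatch")
    labels = np.empty(len(values), dtype=object)
    for s in pd.unique(strata):
        idx = np.flatnonzero(strata == s)
        if len(idx) < 2:
            raise ValueError(f"stratum {s!r} has fewer than 2 animals")
        v = values[idx]
        order = np.argsort(v, kind="stable")
        n_low = (len(idx) + 1) // 2  # median element (odd n) goes low
        lab = np.full(len(idx), "high", dtype=object)
        lab[order[:n_low]] = "low"
        labels[idx] = lab
    return labels


def trait_correlations(table: pd.DataFrame, traits: Sequence[str] = TRAITS) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix (and two-sided p-values) among traits."""
    if len(table) < 3:
        raise ValueError("need at least 3 animals for correlations")
    k = len(traits)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x = table[traits[i]].to_numpy(float)
            y = table[traits[j]].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                warnings.warn(f"zero-variance trait in pair ({traits[i]}, {traits[j]})")
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = list(traits)
    return pd.DataFrame(r, index=idx, columns=idx), pd.DataFrame(p, index=idx, columns=idx)


def build_phenotype_table(records: Sequence[AnimalRecord]) -> pd.DataFrame:
    """Derive the full phenotype table from raw animal records.

    Animals with non-positive ADG are excluded (with a warning) because
    FCR is undefined for them.
    """
    rows = []
    for rec in records:
        adg, mid_bw, mbw = derive_adg(rec.bw_series)
        dfi = float(np.mean(rec.dmi_daily))
        if adg <= 0:
            logger.warning("animal %s excluded: non-positive ADG %.4f", rec.animal_id, adg)
            continue
        rows.append({
            "animal_id": rec.animal_id, "breed": rec.breed, "diet": rec.diet,
            "year": rec.year, "additive": rec.additive,
            "DFI": dfi, "ADG": adg, "FCR": derive_fcr(dfi, adg),
            "MBW": mbw, "fat_depth": rec.fat_depth,
        })
    table = pd.DataFrame(rows)
    table["RFI"] = derive_rfi(table)
    return table[PHENOTYPE_COLUMNS]


def class6_labels(table: pd.DataFrame) -> pd.Series:
    """Combined breed x diet x year class (the fixed-effect factor)."""
    return (table["breed"].astype(str) + "|" + table["diet"].astype(str)
            + "|" + table["year"].astype(str)).rename("class6")


def add_group_labels(table: pd.DataFrame, traits: Sequence[str] = TRAITS) -> pd.DataFrame:
    """Attach per-trait high/low labels from the stratified median split."""
    out = table.copy()
    strata = class6_labels(table)
    for t in traits:
        out[f"{t}_group"] = median_split(table[t].to_numpy(float), strata.to_numpy())
    return out


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype CSV (schema: animal_id, breed, diet, year, additive,
    DFI, ADG, FCR, RFI, MBW, fat_depth)."""
    table = pd.read_csv(path, dtype={"animal_id": str, "breed": str, "diet": str,
                                     "year": str, "additive": str})
    missing = set(PHENOTYPE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"phenotype file missing columns: {sorted(missing)}")
    return table


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table[PHENOTYPE_COLUMNS].to_csv(path, index=False)
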
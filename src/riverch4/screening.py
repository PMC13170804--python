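"""Driver screening: standardized regressions, subgroup analyses and
rank-sum comparisons between aquatic variables and CH4 responses.

The workflow mirrors a common exploratory protocol: Shapiro-Wilk normality
check with log transform of non-normal variables, Z-score standardization
of both sides, bivariate regression (whose slope equals Pearson r), repeated
globally and within subgroups, plus a population-density gradient curve with
loess smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from riverch4 import synth

#: Aquatic variables screened against the two responses by default.
DEFAULT_PREDICTORS: tuple[str, ...] = (
    "TP",
    "NH4N",
    "TN",
    "NO3N",
    "DOC",
    "DO",
    "water_temp",
    "pH",
    "chl_a",
)
RESPONSES: tuple[str, ...] = ("ch4_conc", "diff_flux")

#: Shapiro-Wilk is evaluated on at most this many values (seeded subsample).
SHAPIRO_MAX_N = 5000

#: Exact rank-sum enumeration is used up to this combined sample size when
#: there are no ties; beyond it (or with ties) the normal approximation with
#: tie correction takes over.
EXACT_RANKSUM_MAX_N = 50


@dataclass(frozen=True)
class CoefficientRecord:
    """One standardized regression coefficient (Z-score scale)."""

    response: str
    predictor: str
    subgroup: str
    coefficient: float
    n_used: int
    p_value: float
    flag: str = ""

    def as_dict(self) -> dict:
        return {
            "response": self.response,
            "predictor": self.predictor,
            "subgroup": self.subgroup,
            "coefficient": self.coefficient,
            "n": self.n_used,
            "p": self.p_value,
            "flag": self.flag,
        }


# ---------------------------------------------------------------------------
# Elementary transforms
# ---------------------------------------------------------------------------


def normality_transform(
    values,
    *,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, str, dict]:
    """Log-transform ``values`` when Shapiro-Wilk rejects normality.

    Returns ``(transformed, flag, meta)`` with flag ``"log"`` or ``"none"``.
    Zeros under the log branch receive an offset of half the smallest
    positive value (recorded in ``meta["offset"]``); negatives are an error.
    Samples larger than ``SHAPIRO_MAX_N`` are subsampled with a fixed seed
    before testing.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("normality_transform needs at least 3 finite values")
    test_x = x
    if x.size > SHAPIRO_MAX_N:
        rng = np.random.default_rng(seed)
        test_x = rng.choice(x, size=SHAPIRO_MAX_N, replace=False)
    _, p = stats.shapiro(test_x)
    if p >= alpha:
        return x, "none", {"shapiro_p": float(p), "offset": 0.0}
    if np.any(x < 0):
        raise ValueError("cannot log-transform negative values")
    offset = 0.0
    if np.any(x == 0):
        positive = x[x > 0]
        if positive.size == 0:
            raise ValueError("cannot log-transform an all-zero vector")
        offset = 0.5 * float(positive.min())
    return np.log(x + offset), "log", {"shapiro_p": float(p), "offset": offset}


def zscore(values) -> np.ndarray:
    """Standardize to sample mean 0, sample sd 1 (ddof=1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("zscore needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zscore undefined for a constant vector")
    return (x - x.mean()) / sd


def standardized_coefficient(
    y,
    x,
    *,
    response: str = "y",
    predictor: str = "x",
    subgroup: str = "all",
) -> CoefficientRecord:
    """Slope of Z-scored ``y`` on Z-scored ``x`` with a two-sided p-value.

    Missing values are removed pairwise.  In this bivariate form the slope
    equals the Pearson correlation.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError("y and x must have equal length")
    mask = np.isfinite(y) & np.isfinite(x)
    y, x = y[mask], x[mask]
    n = int(y.size)
    if n < 3:
        raise ValueError(f"need at least 3 paired values, got {n}")
    res = stats.linregress(zscore(x), zscore(y))
    return CoefficientRecord(
        response=response,
        predictor=predictor,
        subgroup=subgroup,
        coefficient=float(res.slope),
        n_used=n,
        p_value=float(res.pvalue),
    )


# ---------------------------------------------------------------------------
# Table-level screening
# ---------------------------------------------------------------------------

_GROUPING_COLUMNS = {
    "continent": "continent_label",
    "disturbance_type": "landscape_class",
    "impacted_vs_pristine": None,  # derived
}


def _pair_coefficient(
    frame: pd.DataFrame,
    response: str,
    predictor: str,
    subgroup: str,
    *,
    min_n: int,
    transform: bool,
    seed: int,
) -> CoefficientRecord:
    pair = frame[[response, predictor]].dropna()
    n = len(pair)
    if n < max(min_n, 3):
        return CoefficientRecord(response, predictor, subgroup, np.nan, n, np.nan, "low_n")
    y = pair[response].to_numpy(dtype=float)
    x = pair[predictor].to_numpy(dtype=float)
    if transform:
        # variables with negative values (temperatures) stay on the raw scale
        for arr in ("y", "x"):
            vals = y if arr == "y" else x
            try:
                vals, _, _ = normality_transform(vals, seed=seed)
            except ValueError:
                pass
            if arr == "y":
                y = vals
            else:
                x = vals
    try:
        return standardized_coefficient(
            y, x, response=response, predictor=predictor, subgroup=subgroup
        )
    except ValueError:
        return CoefficientRecord(response, predictor, subgroup, np.nan, n, np.nan, "degenerate")


def subgroup_coefficients(
    observations: pd.DataFrame,
    grouping: str,
    *,
    responses: tuple[str, ...] = RESPONSES,
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
    min_n: int = 10,
    transform: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Standardized coefficients per (response, predictor, subgroup).

    ``grouping`` is one of ``continent``, ``disturbance_type`` or
    ``impacted_vs_pristine``.  Subgroups below ``min_n`` paired values are
    emitted with flag ``low_n`` and a NaN coefficient rather than dropped.
    """
    if grouping not in _GROUPING_COLUMNS:
        raise ValueError(
            f"unknown grouping {grouping!r}; expected one of {sorted(_GROUPING_COLUMNS)}"
        )
    if grouping == "impacted_vs_pristine":
        from riverch4.pipeline import is_human_impacted

        labels = np.where(is_human_impacted(observations), "impacted", "pristine")
    else:
        labels = observations[_GROUPING_COLUMNS[grouping]].astype(str).to_numpy()

    records = []
    for subgroup in pd.unique(labels):
        frame = observations.loc[labels == subgroup]
        for response in responses:
            for predictor in predictors:
                if predictor not in frame.columns:
                    continue
                rec = _pair_coefficient(
                    frame, response, predictor, str(subgroup),
                    min_n=min_n, transform=transform, seed=seed,
                )
                records.append(rec.as_dict())
    return pd.DataFrame.from_records(records)


def global_coefficients(
    observations: pd.DataFrame,
    *,
    responses: tuple[str, ...] = RESPONSES,
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
    min_n: int = 10,
    transform: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Whole-table coefficients (subgroup label ``all``)."""
    records = [
        _pair_coefficient(
            observations, response, predictor, "all",
            min_n=min_n, transform=transform, seed=seed,
        ).as_dict()
        for response in responses
        for predictor in predictors
        if predictor in observations.columns
    ]
    return pd.DataFrame.from_records(records)


def density_gradient_curve(
    observations: pd.DataFrame,
    thresholds,
    *,
    response: str = "diff_flux",
    predictor: str = "TP",
    span: float = 0.75,
    min_n: int = 10,
    transform: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Coefficient vs population-density threshold, loess-smoothed.

    For each threshold the coefficient is computed on observations with
    density strictly above it.  Thresholds leaving fewer than ``min_n``
    pairs are flagged and excluded from smoothing.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("at least one threshold required")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")

    rows = []
    for t in thresholds:
        frame = observations.loc[observations["population_density"] > t]
        rec = _pair_coefficient(
            frame, response, predictor, f">{t:g}",
            min_n=min_n, transform=transform, seed=seed,
        )
        rows.append(
            {"threshold": t, "coefficient": rec.coefficient,
             "n": rec.n_used, "p": rec.p_value, "flag": rec.flag}
        )
    curve = pd.DataFrame(rows)

    ok = curve["flag"] == ""
    curve["smoothed"] = np.nan
    if ok.sum() >= 2:
        smoothed = sm.nonparametric.lowess(
            curve.loc[ok, "coefficient"],
            curve.loc[ok, "threshold"],
            frac=span,
            return_sorted=False,
        )
        curve.loc[ok, "smoothed"] = smoothed
    return curve


# ---------------------------------------------------------------------------
# Rank-sum comparison
# ---------------------------------------------------------------------------


def wilcoxon_compare(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when there are no ties and
    ``n + m <= EXACT_RANKSUM_MAX_N``; otherwise the normal approximation
    with tie correction.  Returns ``(U statistic of a, p)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    if not has_ties and combined.size <= EXACT_RANKSUM_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
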
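"""Per-ROI characterization: factor-dose correlation screen and demographic
disparity tests.

The screen flags factors whose Pearson correlation with dose among the
ROI's members reaches at least a weak effect (|PCC| >= 0.2 by default).
Disparity testing compares each demographic variable's category counts in
the ROI against expectations derived from the whole cohort's proportions
(one-sample chi-square goodness of fit, df = k - 1), pooling categories
whose expected count falls below 5 — the usual validity condition for the
chi-square approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationScreenResult",
    "DisparityResult",
    "correlation_screen",
    "chi_square_disparity",
    "disparity_table",
    "significance_stars",
    "profile_roi",
]

POOLED_LABEL = "other"


@dataclass
class CorrelationScreenResult:
    roi_id: str
    factor_id: str
    pcc: float
    flagged: bool
    computable: bool = True


@dataclass
class DisparityResult:
    roi_id: str
    variable: str
    categories: list[str]
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p_value: float
    significant: bool
    testable: bool = True

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value) if self.testable else "-"


def significance_stars(p: float) -> str:
    """Fig-style significance markers: - / * / ** / *** at 0.05/0.01/0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "-"


def correlation_screen(
    roi,
    scores: pd.DataFrame,
    dose: pd.Series,
    cutoff: float = 0.2,
) -> list[CorrelationScreenResult]:
    """Pearson correlation of every factor with dose inside one ROI.

    Factors with constant values (or a constant dose) within the ROI are
    reported as not computable and never flagged.
    """
    members = np.asarray(roi.member_indices, dtype=int)
    if len(members) < 3:
        raise ValueError("correlation screen needs at least 3 ROI members")
    d = dose.to_numpy()[members].astype(float)
    results = []
    dose_constant = np.ptp(d) == 0
    for f in scores.columns:
        x = scores[f].to_numpy()[members].astype(float)
        if dose_constant or np.ptp(x) == 0:
            results.append(
                CorrelationScreenResult(roi.roi_id, f, np.nan, False, False)
            )
            continue
        pcc = float(stats.pearsonr(x, d).statistic)
        results.append(
            CorrelationScreenResult(roi.roi_id, f, pcc, abs(pcc) >= cutoff)
        )
    return results


def _pool_categories(
    categories: list[str], observed: np.ndarray, expected: np.ndarray
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Pool categories until every expected count is >= 5.

    Categories with expected < 5 are merged into an ``other`` bucket; if
    that bucket itself stays below 5 it absorbs the smallest-expected
    remaining category, repeatedly.
    """
    cats = list(categories)
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    small = exp < 5
    if small.sum() >= 1:
        pooled_obs = obs[small].sum()
        pooled_exp = exp[small].sum()
        cats = [c for c, s in zip(cats, small) if not s]
        obs = obs[~small]
        exp = exp[~small]
        while pooled_exp < 5 and len(cats) > 0:
            j = int(np.argmin(exp))
            pooled_obs += obs[j]
            pooled_exp += exp[j]
            cats.pop(j)
            obs = np.delete(obs, j)
            exp = np.delete(exp, j)
        cats.append(POOLED_LABEL)
        obs = np.append(obs, pooled_obs)
        exp = np.append(exp, pooled_exp)
    return cats, obs, exp


def chi_square_disparity(
    roi,
    variable: str,
    roi_values: pd.Series,
    cohort_values: pd.Series,
    alpha: float = 0.05,
) -> DisparityResult:
    """Chi-square goodness-of-fit of a ROI's category counts against the cohort.

    The null frequencies are the whole cohort's category proportions (the
    ROI members included) scaled to the ROI size. Expected counts below 5
    are pooled before testing; fewer than two post-pooling categories make
    the variable untestable for this ROI.
    """
    cohort_counts = cohort_values.value_counts()
    if len(cohort_counts) < 2:
        raise ValueError(f"variable {variable!r} has < 2 categories in the cohort")
    categories = [str(c) for c in cohort_counts.index]
    props = cohort_counts.to_numpy(dtype=float) / len(cohort_values)
    n_roi = len(roi_values)
    roi_counts = roi_values.astype(str).value_counts()
    observed = np.array([float(roi_counts.get(c, 0)) for c in categories])
    expected = props * n_roi

    cats, obs, exp = _pool_categories(categories, observed, expected)
    if len(cats) < 2:
        return DisparityResult(
            roi_id=roi.roi_id,
            variable=variable,
            categories=cats,
            observed=obs,
            expected=exp,
            chi2=np.nan,
            df=0,
            p_value=np.nan,
            significant=False,
            testable=False,
        )
    chi2, p = stats.chisquare(f_obs=obs, f_exp=exp)
    return DisparityResult(
        roi_id=roi.roi_id,
        variable=variable,
        categories=cats,
        observed=obs,
        expected=exp,
        chi2=float(chi2),
        df=len(cats) - 1,
        p_value=float(p),
        significant=bool(p < alpha),
    )


def disparity_table(
    roi,
    demographics: pd.DataFrame,
    *,
    alpha: float = 0.05,
    adjust: str = "none",
) -> list[DisparityResult]:
    """Disparity tests for every demographic variable for one ROI.

    ``adjust="bh"`` applies a Benjamini-Hochberg correction across the
    variables before calling significance (off by default, matching raw
    per-variable testing at alpha).
    """
    if adjust not in ("none", "bh"):
        raise ValueError("adjust must be 'none' or 'bh'")
    members = np.asarray(roi.member_indices, dtype=int)
    results = [
        chi_square_disparity(
            roi,
            var,
            demographics[var].iloc[members],
            demographics[var],
            alpha=alpha,
        )
        for var in demographics.columns
    ]
    if adjust == "bh":
        testable = [r for r in results if r.testable]
        if testable:
            pvals = np.array([r.p_value for r in testable])
            reject = stats.false_discovery_control(pvals) < alpha
            for r, rej in zip(testable, reject):
                r.significant = bool(rej)
    return results


def profile_roi(
    roi,
    screen_results: list[CorrelationScreenResult],
    disparity_results: list[DisparityResult],
    demographics: pd.DataFrame,
) -> dict:
    """Bundle one ROI's dose summary, flagged factors and significant
    demographics with ROI-vs-cohort category proportions (pie-chart data)."""
    members = np.asarray(roi.member_indices, dtype=int)
    pies = {}
    for res in disparity_results:
        if not (res.testable and res.significant):
            continue
        var = res.variable
        cohort = demographics[var].astype(str)
        sub = cohort.iloc[members]
        cats = sorted(cohort.unique())
        pies[var] = {
            "stars": res.stars,
            "p_value": res.p_value,
            "categories": cats,
            "cohort_proportions": [float((cohort == c).mean()) for c in cats],
            "roi_proportions": [float((sub == c).mean()) for c in cats],
        }
    return {
        "roi_id": roi.roi_id,
        "n": int(roi.n),
        "dose_mean": roi.dose_mean,
        "dose_sd": roi.dose_sd,
        "flagged_factors": [
            {"factor_id": r.factor_id, "pcc": r.pcc}
            for r in screen_results
            if r.flagged
        ],
        "significant_demographics": pies,
    }
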
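"""Maximum fold change, extrema-anchored paired testing and ranking.

The effect size of a metabolite's time course is the *maximum fold
change* (MFC): the ratio of the extreme concentrations of its cohort
median curve, oriented by which extremum occurs first —

    if conc_min_index < conc_max_index:  MFC = conc_max / conc_min  (>= 1)
    else:                                MFC = conc_min / conc_max  (<= 1)

Significance comes from a Wilcoxon signed-rank test on the per-subject
interpolated concentrations at the two extremal grid positions, with
Benjamini-Hochberg FDR adjustment across the panel.  A Shapiro-Wilk
screen documents (non-)normality at the extrema but never switches the
test: ranks keep metabolites comparable.  Candidates are called moderate
predictors above MFC 1.20 and strong above 1.40, at adjusted P < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .preprocess import InterpolatedCurve, MedianCurve

#: Default selection thresholds.
ALPHA = 0.001
MODERATE_CUT = 1.20
STRONG_CUT = 1.40
MIN_PAIRS = 6
EXACT_MAX_N = 25


@dataclass(frozen=True)
class ExtremaResult:
    """Grid indices and values of a median curve's global extrema."""

    metabolite: str
    idx_min: int
    idx_max: int
    conc_min: float
    conc_max: float


def locate_extrema(median: MedianCurve) -> ExtremaResult:
    """Global minimum and maximum of the median curve, earliest index on ties."""
    v = np.asarray(median.values, dtype=float)
    if np.isnan(v).any():
        raise ValueError(f"median curve for {median.metabolite!r} has undefined points")
    idx_min = int(np.argmin(v))  # np.arg* return the first occurrence
    idx_max = int(np.argmax(v))
    return ExtremaResult(median.metabolite, idx_min, idx_max, float(v[idx_min]), float(v[idx_max]))


def compute_mfc(extrema: ExtremaResult) -> float:
    """Directional maximum fold change of a median curve.

    >= 1 when the minimum precedes the maximum, <= 1 when the maximum
    comes first, exactly 1 for a constant curve (coincident extrema).
    """
    if extrema.idx_min == extrema.idx_max:
        return 1.0
    if extrema.conc_min <= 0:
        raise ValueError(f"{extrema.metabolite}: non-positive minimum concentration")
    if extrema.idx_min < extrema.idx_max:
        return extrema.conc_max / extrema.conc_min
    return extrema.conc_min / extrema.conc_max


def paired_samples_at_extrema(
    curves: list[InterpolatedCurve], extrema: ExtremaResult
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-subject interpolated values at the extremal grid positions.

    Only subjects whose observed support covers both indices contribute;
    the number of dropped subjects is returned alongside the pairs.
    """
    x, y, dropped = [], [], 0
    for c in curves:
        vmin, vmax = c.values[extrema.idx_min], c.values[extrema.idx_max]
        if np.isnan(vmin) or np.isnan(vmax):
            dropped += 1
            continue
        x.append(vmin)
        y.append(vmax)
    return np.asarray(x), np.asarray(y), dropped


def normality_screen(values: np.ndarray, alpha: float = 0.01) -> tuple[str, float]:
    """Shapiro-Wilk screen, report-only.

    Returns ``("pass"|"fail"|"not assessed", W)``; degenerate samples
    (n < 3 or constant) are not assessed.  The pipeline always proceeds
    nonparametrically regardless of the outcome.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3 or np.allclose(values, values[0]):
        return "not assessed", float("nan")
    w, p = sps.shapiro(values)
    return ("pass" if p >= alpha else "fail"), float(w)


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, str]:
    """Two-sided Wilcoxon signed-rank P for paired samples.

    Zero differences are dropped (the classic treatment), remaining ties
    are mid-ranked.  The exact null distribution is used for n <= 25
    without ties in |d|; otherwise the normal approximation with
    continuity correction.  Returns ``(p, branch)`` with branch in
    {"exact", "approx", "degenerate"}.
    """
    d = np.asarray(y, dtype=float) - np.asarray(x, dtype=float)
    d = d[d != 0.0]
    if len(d) == 0:
        return 1.0, "degenerate"
    has_ties = len(np.unique(np.abs(d))) < len(d)
    if len(d) <= EXACT_MAX_N and not has_ties:
        res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method="exact")
        return float(res.pvalue), "exact"
    res = sps.wilcoxon(
        d, zero_method="wilcox", alternative="two-sided", method="approx", correction=True
    )
    return float(res.pvalue), "approx"


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def classify_predictor(
    mfc: float,
    p_adj: float,
    alpha: float = ALPHA,
    moderate_cut: float = MODERATE_CUT,
    strong_cut: float = STRONG_CUT,
) -> str:
    """Predictor strength from effect size and adjusted significance.

    The effective magnitude max(MFC, 1/MFC) treats decreasing metabolites
    symmetrically.  Strong above ``strong_cut``, moderate above
    ``moderate_cut``, both requiring adjusted P below ``alpha``.
    """
    magnitude = max(mfc, 1.0 / mfc)
    if magnitude > strong_cut and p_adj < alpha:
        return "strong"
    if magnitude > moderate_cut and p_adj < alpha:
        return "moderate"
    return "none"


def biomarker_table(
    curves: dict[str, list[InterpolatedCurve]],
    medians: dict[str, MedianCurve],
    alpha: float = ALPHA,
    moderate_cut: float = MODERATE_CUT,
    strong_cut: float = STRONG_CUT,
    min_pairs: int = MIN_PAIRS,
) -> pd.DataFrame:
    """Full biomarker ranking: one row per metabolite, MFC-descending.

    Columns: metabolite, mfc, log2_mfc, p_raw, p_adj, neglog10_p,
    predictor_class, test_branch, n_pairs, n_dropped and the report-only
    Shapiro-Wilk flags at the two extrema.
    """
    rows = []
    for metabolite, median in medians.items():
        ext = locate_extrema(median)
        mfc = compute_mfc(ext)
        x, y, dropped = paired_samples_at_extrema(curves[metabolite], ext)
        flag_min, _ = normality_screen(x)
        flag_max, _ = normality_screen(y)
        if ext.idx_min == ext.idx_max:
            p_raw, branch = 1.0, "degenerate"
        elif len(x) < min_pairs:
            p_raw, branch = float("nan"), "skipped"
        else:
            p_raw, branch = wilcoxon_signed_rank(x, y)
        rows.append(
            {
                "metabolite": metabolite,
                "mfc": mfc,
                "idx_min": ext.idx_min,
                "idx_max": ext.idx_max,
                "p_raw": p_raw,
                "test_branch": branch,
                "n_pairs": len(x),
                "n_dropped": dropped,
                "shapiro_min": flag_min,
                "shapiro_max": flag_max,
            }
        )
    table = pd.DataFrame(rows)
    usable = table["p_raw"].notna()
    table["p_adj"] = np.nan
    table.loc[usable, "p_adj"] = fdr_adjust(table.loc[usable, "p_raw"].to_numpy())
    table["log2_mfc"] = np.log2(table["mfc"])
    with np.errstate(divide="ignore"):
        table["neglog10_p"] = -np.log10(table["p_adj"])
    table["predictor_class"] = [
        classify_predictor(m, p, alpha, moderate_cut, strong_cut) if np.isfinite(p) else "none"
        for m, p in zip(table["mfc"], table["p_adj"])
    ]
    order = ["metabolite", "mfc", "log2_mfc", "p_raw", "p_adj", "neglog10_p", "predictor_class"]
    rest = [c for c in table.columns if c not in order]
    return (
        table[order + rest]
        .sort_values("mfc", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def volcano_table(records: pd.DataFrame) -> pd.DataFrame:
    """The volcano plot's exact data: effect size vs significance."""
    return records[["metabolite", "log2_mfc", "neglog10_p", "predictor_class"]].copy()
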
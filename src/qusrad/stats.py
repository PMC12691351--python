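"""Univariate screening of selected features with Bonferroni correction.

Each feature is compared between the low-risk and intermediate-to-high
risk groups with either a Welch two-sample t-test (both groups pass the
Shapiro-Wilk normality check) or a two-sided Mann-Whitney U test.
Significance is flagged both at the raw 0.05 level and at the
Bonferroni-adjusted level alpha / n_tests (0.001 for the default pool
of 50 MRMR-selected features).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import StatsConfig

__all__ = ["choose_test", "screen_features", "ScreenResult"]


@dataclass
class ScreenResult:
    table: pd.DataFrame  # feature, test, p, raw_pass, bonferroni_pass, summaries
    adjusted_alpha: float

    def significant(self, adjusted: bool = True) -> pd.DataFrame:
        col = "bonferroni_pass" if adjusted else "raw_pass"
        return self.table[self.table[col]]


def choose_test(
    group0: np.ndarray, group1: np.ndarray, normality_alpha: float = 0.05
) -> str:
    """'t' (Welch) when both groups look Gaussian under Shapiro-Wilk,
    otherwise 'mann-whitney'.  Constant groups (Shapiro undefined) fall
    back to the rank test."""
    group0 = np.asarray(group0, dtype=float)
    group1 = np.asarray(group1, dtype=float)
    if min(len(group0), len(group1)) < 3:
        raise ValueError("need at least 3 samples per group")
    for g in (group0, group1):
        if np.ptp(g) == 0:
            return "mann-whitney"
        if sps.shapiro(g).pvalue <= normality_alpha:
            return "mann-whitney"
    return "t"


def _one_feature(x0: np.ndarray, x1: np.ndarray, cfg: StatsConfig) -> tuple[str, float]:
    test = choose_test(x0, x1, cfg.normality_alpha)
    if test == "t":
        p = float(sps.ttest_ind(x0, x1, equal_var=False).pvalue)
    else:
        # scipy's "auto" uses the exact distribution for small tie-free
        # samples and the tie-corrected normal approximation otherwise
        p = float(sps.mannwhitneyu(x0, x1, alternative="two-sided").pvalue)
    return test, p


def screen_features(
    X: pd.DataFrame,
    y: np.ndarray,
    cfg: StatsConfig | None = None,
) -> ScreenResult:
    """Test every column of ``X`` between the two label groups.

    ``cfg.n_tests`` defaults to the number of columns screened when not
    matching, so the Bonferroni threshold always reflects the family
    actually tested.
    """
    cfg = cfg or StatsConfig()
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both groups must be non-empty")
    n_tests = cfg.n_tests if cfg.n_tests > 0 else X.shape[1]
    adjusted_alpha = cfg.alpha / n_tests
    rows = []
    for col in X.columns:
        x0 = X.loc[y == 0, col].to_numpy(dtype=float)
        x1 = X.loc[y == 1, col].to_numpy(dtype=float)
        test, p = _one_feature(x0, x1, cfg)
        rows.append(
            {
                "feature": col,
                "test": test,
                "p": p,
                "raw_pass": p < cfg.alpha,
                "bonferroni_pass": p < adjusted_alpha,
                "median_low": float(np.median(x0)),
                "iqr_low": float(np.subtract(*np.percentile(x0, [75, 25]))),
                "median_high": float(np.median(x1)),
                "iqr_high": float(np.subtract(*np.percentile(x1, [75, 25]))),
            }
        )
    table = pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)
    return ScreenResult(table=table, adjusted_alpha=adjusted_alpha)
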
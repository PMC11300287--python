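"""Assumption-gated group statistics on the lesion hypoxia fraction.

Two-sample comparisons (low vs high grade group, pTstage 2 vs 3) use a
t-test only when both groups pass Shapiro-Wilk normality AND Levene's
homogeneity test at the same alpha; otherwise the Mann-Whitney U test.
The five-grade analysis uses Kruskal-Wallis with tie correction, and the
grade trend a Pearson correlation with pGG coded numerically 1-5 (Spearman
available as an option). All tests are two-sided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)

GROUPINGS = ("pGG_low_vs_high", "pTstage_2_vs_3", "pGG_1_to_5")


@dataclass
class GroupComparison:
    grouping: str
    test_used: str  # t_test | mann_whitney | kruskal_wallis | pearson
    statistic: float
    p_value: float
    group_medians: list[tuple[str, float]] = field(default_factory=list)
    group_sizes: list[tuple[str, int]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "grouping": self.grouping,
            "test_used": self.test_used,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "group_medians": {k: v for k, v in self.group_medians},
            "group_sizes": {k: v for k, v in self.group_sizes},
        }


def _shapiro_p(values: np.ndarray) -> float:
    # degenerate / near-constant samples are treated as non-normal
    if np.ptp(values) == 0:
        return 0.0
    try:
        return float(stats.shapiro(values).pvalue)
    except Exception:
        return 0.0


def choose_two_sample_test(group_a, group_b, alpha: float = 0.05) -> str:
    """Gate: t-test iff both Shapiro-Wilk p >= alpha and Levene p >= alpha."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValidationError("each group needs at least 3 values")
    normal = _shapiro_p(a) >= alpha and _shapiro_p(b) >= alpha
    if normal:
        try:
            homogeneous = stats.levene(a, b).pvalue >= alpha
        except Exception:
            homogeneous = False
    else:
        homogeneous = False
    choice = "t_test" if (normal and homogeneous) else "mann_whitney"
    logger.debug("gate: normal=%s homogeneous=%s -> %s", normal, homogeneous, choice)
    return choice


def _two_sample(a, b, test: str) -> tuple[float, float]:
    if test == "t_test":
        res = stats.ttest_ind(a, b, equal_var=True)
    elif test == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    else:
        raise ValidationError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    hf_table: pd.DataFrame,
    grouping: str,
    alpha: float = 0.05,
    force_test: str | None = None,
) -> GroupComparison:
    """Gated two-sample comparison of HF_DWI between clinical groups.

    ``hf_table``: one row per patient with ``hf_dwi`` plus ``pGG`` /
    ``pTstage`` (use the index lesion per patient). ``grouping`` is
    ``pGG_low_vs_high`` (pGG < 3 vs >= 3) or ``pTstage_2_vs_3``.
    """
    if grouping == "pGG_low_vs_high":
        sel = hf_table["pGG"] >= 3
        labels = ("pGG<3", "pGG>=3")
    elif grouping == "pTstage_2_vs_3":
        sel = hf_table["pTstage"] == 3
        labels = ("pTstage=2", "pTstage=3")
    else:
        raise ValidationError(f"grouping must be one of {GROUPINGS[:2]}")
    a = hf_table.loc[~sel, "hf_dwi"].to_numpy(dtype=float)
    b = hf_table.loc[sel, "hf_dwi"].to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError(f"empty group in {grouping}")
    test = force_test or choose_two_sample_test(a, b, alpha)
    statistic, p = _two_sample(a, b, test)
    return GroupComparison(
        grouping=grouping,
        test_used=test,
        statistic=statistic,
        p_value=p,
        group_medians=[(labels[0], float(np.median(a))),
                       (labels[1], float(np.median(b)))],
        group_sizes=[(labels[0], int(a.size)), (labels[1], int(b.size))],
    )


def kruskal_wallis_by_grade(hf_by_grade: dict[int, np.ndarray]) -> GroupComparison:
    """Kruskal-Wallis H over the non-empty grade groups (tie-corrected).

    All-identical values across groups give H = 0, p = 1 rather than an
    error (no evidence of a difference, not a failure).
    """
    groups = {g: np.asarray(v, dtype=float)
              for g, v in sorted(hf_by_grade.items()) if len(v) > 0}
    if len(groups) < 2:
        raise ValidationError("need at least 2 non-empty grade groups")
    values = list(groups.values())
    pooled = np.concatenate(values)
    if np.ptp(pooled) == 0:
        statistic, p = 0.0, 1.0
    else:
        res = stats.kruskal(*values)
        statistic, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        grouping="pGG_1_to_5",
        test_used="kruskal_wallis",
        statistic=statistic,
        p_value=p,
        group_medians=[(f"pGG={g}", float(np.median(v))) for g, v in groups.items()],
        group_sizes=[(f"pGG={g}", int(v.size)) for g, v in groups.items()],
    )


def pearson_hf_vs_grade(hf, pgg, method: str = "pearson") -> tuple[float, float]:
    """Correlation of HF_DWI with grade group coded 1-5 (two-sided p)."""
    hf = np.asarray(hf, dtype=float)
    pgg = np.asarray(pgg, dtype=float)
    if hf.size != pgg.size or hf.size < 3:
        raise ValidationError("need >= 3 paired (hf, pGG) values")
    if np.ptp(hf) == 0 or np.ptp(pgg) == 0:
        raise ValidationError("correlation undefined: a variable has zero variance")
    if method == "pearson":
        res = stats.pearsonr(hf, pgg)
    elif method == "spearman":
        res = stats.spearmanr(hf, pgg)
    else:
        raise ValidationError("method must be 'pearson' or 'spearman'")
    return float(res.statistic), float(res.pvalue)
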
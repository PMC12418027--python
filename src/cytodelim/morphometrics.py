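"""Trait comparisons and the determination-key classifier.

Leaflet dimensions of the diploid and tetraploid lineages are compared with
the Wilcoxon rank-sum (Mann-Whitney) test on untransformed measurements;
male-flower diameters and elevations with a t test (Welch by default, since
equal variances are not assumed). A small rule-based classifier applies the
printed determination key: each provided character (leaflet count, stamen
count, flower diameter, flowering month) votes for the species whose range it
falls in, and a specimen is assigned only on a unanimous, non-empty vote.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    n_x: int
    n_y: int
    mode: str  # "two-sided", "less", "greater"
    method: str = ""  # "exact" or "normal-approximation" for the rank-sum test
    df: float | None = None

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_x": self.n_x,
            "n_y": self.n_y,
            "mode": self.mode,
            "method": self.method,
            "df": self.df,
        }


def wilcoxon_rank_sum(
    x, y, mode: str = "two-sided", method: str = "auto"
) -> GroupComparison:
    """Wilcoxon rank-sum test; statistic is the rank sum W of ``x`` (midranks).

    ``method="auto"`` uses exact enumeration over rank assignments when
    n_x + n_y <= 12 and there are no ties, otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both samples; p = 1")
        w = float(len(x) * (len(pooled) + 1) / 2.0)
        return GroupComparison("wilcoxon_rank_sum", w, 1.0, len(x), len(y), mode,
                               method="degenerate")
    if method == "auto":
        method = "exact" if (len(pooled) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=mode, method=method,
                             use_continuity=True)
    # U statistic of x -> rank-sum W of x
    w = float(res.statistic + len(x) * (len(x) + 1) / 2.0)
    return GroupComparison(
        "wilcoxon_rank_sum", w, float(res.pvalue), len(x), len(y), mode,
        method={"exact": "exact", "asymptotic": "normal-approximation"}[method],
    )


def t_test(x, y, variant: str = "welch", mode: str = "two-sided") -> GroupComparison:
    """Two-sample t test; Welch (unequal variances) by default."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if np.isclose(x.mean(), y.mean()):
            warnings.warn("zero variance in both samples with equal means; p = 1")
            return GroupComparison("t_test", 0.0, 1.0, len(x), len(y), mode,
                                   method=variant, df=float(len(x) + len(y) - 2))
        raise ValueError("zero variance in both samples with different means")
    if variant not in {"welch", "student"}:
        raise ValueError("variant must be 'welch' or 'student'")
    res = stats.ttest_ind(x, y, equal_var=(variant == "student"), alternative=mode)
    return GroupComparison(
        "t_test", float(res.statistic), float(res.pvalue), len(x), len(y), mode,
        method=variant, df=float(res.df),
    )


def leaflet_pair_tabulate(traits: pd.DataFrame) -> pd.DataFrame:
    """Per-species counts of compound leaves by leaflet-pair number.

    Expects columns ``species`` and ``pairs``; rows are species, columns the
    observed pair numbers, values counts. Row sums equal leaves measured.
    """
    if "pairs" not in traits.columns:
        raise ValueError("trait table lacks a 'pairs' column")
    if traits.empty:
        return pd.DataFrame()
    tab = pd.crosstab(traits["species"], traits["pairs"])
    tab.columns.name = "pairs"
    return tab


# Character ranges from the printed determination key. Boundaries inclusive;
# values inside both ranges (9 leaflets, a 4.0 mm flower, flowering in May)
# leave that character indecisive.
KEY_RANGES = {
    "C. paliurus": {
        "leaflet_count": (5, 9),
        "stamen_count": (30, 35),
        "flower_diameter_mm": (4.0, 6.0),
        "flowering_months": (4, 5),  # mid-April - early May
    },
    "C. serrata": {
        "leaflet_count": (9, 13),
        "stamen_count": (18, 20),
        "flower_diameter_mm": (3.0, 4.0),
        "flowering_months": (5, 6),  # mid-May - early June
    },
}


def classify_specimen(
    leaflet_count: int | None = None,
    stamen_count: int | None = None,
    flower_diameter_mm: float | None = None,
    flowering_month: int | None = None,
) -> tuple[str, dict[str, list[str]]]:
    """Assign a specimen by the determination key.

    Returns ``(label, votes)`` where ``label`` is a species name or
    ``"ambiguous"`` and ``votes`` maps each provided character to the species
    it is consistent with. A species is returned only when every decisive
    character (one consistent with exactly one species) names the same
    species; an out-of-range character contradicts both and forces ambiguity.
    """
    provided = {
        "leaflet_count": leaflet_count,
        "stamen_count": stamen_count,
        "flower_diameter_mm": flower_diameter_mm,
        "flowering_months": flowering_month,
    }
    provided = {k: v for k, v in provided.items() if v is not None}
    if not provided:
        raise ValueError("at least one character must be provided")
    for name in ("leaflet_count", "stamen_count"):
        if name in provided and provided[name] < 0:
            raise ValueError(f"{name} must be non-negative")
    if "flower_diameter_mm" in provided and provided["flower_diameter_mm"] <= 0:
        raise ValueError("flower_diameter_mm must be positive")

    votes: dict[str, list[str]] = {}
    for char, value in provided.items():
        consistent = [
            sp for sp, ranges in KEY_RANGES.items()
            if ranges[char][0] <= value <= ranges[char][1]
        ]
        votes[char] = consistent

    decisive = [v[0] for v in votes.values() if len(v) == 1]
    if decisive and all(d == decisive[0] for d in decisive):
        # a contradiction (empty vote) elsewhere still blocks assignment
        if all(len(v) > 0 for v in votes.values()):
            return decisive[0], votes
    return "ambiguous", votes
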
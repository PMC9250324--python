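"""Statistical layer for search-strategy and traditional-measure analyses.

Pools the ten categories into the direct (A-D), indirect (E-G), and
non-effective (H-J) sets, compares cohorts with the chi-square test on the
pooled frequency table, quantifies rater agreement with Cohen's kappa, and
wraps the classical nonparametric tests (Mann-Whitney U, Friedman with
Bonferroni-corrected pairwise post-hocs, Kolmogorov-Smirnov normality).
All tests are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.diagnostic import lilliefors

from .strategy import CATEGORIES, SSALabel

__all__ = [
    "POOLED_SETS",
    "StrategyFrequencies",
    "AgreementResult",
    "pool_strategies",
    "chi_square_pooled",
    "cohens_kappa",
    "mann_whitney_u",
    "friedman_bonferroni",
    "ks_normality",
    "summarize",
]

#: The three pooled strategy sets.
POOLED_SETS: Dict[str, Tuple[str, ...]] = {
    "direct": tuple("ABCD"),
    "indirect": tuple("EFG"),
    "non_effective": tuple("HIJ"),
}

_SET_OF = {cat: name for name, cats in POOLED_SETS.items() for cat in cats}


@dataclass(frozen=True)
class StrategyFrequencies:
    """Per-category and pooled strategy counts for one group of trials."""

    counts: pd.Series  # index A..J
    keys: dict

    @property
    def pooled(self) -> pd.Series:
        return pd.Series(
            {name: int(self.counts[list(cats)].sum()) for name, cats in POOLED_SETS.items()},
            name="n",
        )

    @property
    def n_trials(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class AgreementResult:
    """Chance-corrected agreement between two raters."""

    kappa: float
    n_items: int
    table: pd.DataFrame  # rater1 x rater2 confusion table


def _categories_of(labels: Iterable) -> List[str]:
    out = []
    for lab in labels:
        cat = lab.category if isinstance(lab, SSALabel) else str(lab)
        if cat not in CATEGORIES:
            raise ValueError(f"unknown strategy category {cat!r}")
        out.append(cat)
    return out


def pool_strategies(labels: Iterable, **keys) -> StrategyFrequencies:
    """Tally raw A-J and pooled direct/indirect/non-effective counts."""
    cats = _categories_of(labels)
    counts = pd.Series(0, index=list(CATEGORIES), name="n", dtype=int)
    for c in cats:
        counts[c] += 1
    return StrategyFrequencies(counts=counts, keys=keys)


def chi_square_pooled(
    f1: StrategyFrequencies,
    f2: StrategyFrequencies,
    raw_categories: bool = False,
) -> Tuple[float, int, float]:
    """Pearson chi-square comparing two groups' strategy distributions.

    Uses the pooled 2x3 table by default (2 x 10 with ``raw_categories``),
    without continuity correction.  Categories empty in both groups are
    dropped (with a warning) and the degrees of freedom adjusted.
    Identical distributions give a statistic of exactly 0 and p = 1.
    """
    a = f1.counts if raw_categories else f1.pooled
    b = f2.counts if raw_categories else f2.pooled
    table = np.vstack([a.to_numpy(dtype=float), b.to_numpy(dtype=float)])
    keep = table.sum(axis=0) > 0
    if not keep.all():
        dropped = list(np.asarray(a.index)[~keep])
        warnings.warn(f"dropping empty categories from chi-square table: {dropped}", stacklevel=2)
        table = table[:, keep]
    if table.shape[1] < 2 or table.sum() == 0:
        raise ValueError("chi-square needs at least two non-empty categories")
    stat, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p)


def cohens_kappa(r1: Sequence, r2: Sequence) -> AgreementResult:
    """Cohen's kappa between two raters' category assignments.

    kappa = (p_o - p_e) / (1 - p_e), with chance agreement p_e from the
    rater marginals; 1.0 iff the raters agree on every item.
    """
    c1, c2 = _categories_of(r1), _categories_of(r2)
    if len(c1) != len(c2):
        raise ValueError("rater vectors must have equal length")
    if not c1:
        raise ValueError("empty rating vectors")
    alphabet = sorted(set(c1) | set(c2))
    table = pd.crosstab(
        pd.Categorical(c1, categories=alphabet),
        pd.Categorical(c2, categories=alphabet),
        dropna=False,
    )
    table.index.name, table.columns.name = "rater1", "rater2"
    if c1 == c2:
        kappa = 1.0  # perfect agreement, even if a single category was used
    else:
        kappa = float(cohen_kappa_score(c1, c2, labels=alphabet))
    return AgreementResult(kappa=kappa, n_items=len(c1), table=table)


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U test (midranks for ties)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two observations")
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def friedman_bonferroni(matrix) -> Tuple[float, float, pd.DataFrame]:
    """Friedman test across conditions (columns) over blocks (rows), with
    Bonferroni-corrected pairwise Wilcoxon signed-rank post-hocs.

    ``matrix`` is blocks x conditions (e.g. animals x days) and must be
    complete.  The adjusted p is the raw pairwise p times the number of
    comparisons, capped at 1.  A constant matrix yields statistic 0, p 1.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 3:
        raise ValueError("need a complete blocks x conditions matrix with >=3 conditions")
    if not np.all(np.isfinite(m)):
        raise ValueError("incomplete blocks are not supported")
    names = list(matrix.columns) if isinstance(matrix, pd.DataFrame) else list(range(m.shape[1]))
    if np.allclose(m, m[:, [0]]):
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.friedmanchisquare(*(m[:, j] for j in range(m.shape[1])))
    pairs = list(combinations(range(m.shape[1]), 2))
    rows = []
    for i, j in pairs:
        d = m[:, i] - m[:, j]
        if np.allclose(d, 0):
            raw = 1.0
        else:
            raw = float(sps.wilcoxon(m[:, i], m[:, j], zero_method="wilcox").pvalue)
        rows.append(
            {
                "a": names[i],
                "b": names[j],
                "p_raw": raw,
                "p_adjusted": min(1.0, raw * len(pairs)),
            }
        )
    return float(stat), float(p), pd.DataFrame(rows)


def ks_normality(sample: Sequence[float]) -> Tuple[float, float]:
    """Kolmogorov-Smirnov normality test (Lilliefors: mean and variance
    estimated from the sample, as statistics packages do by default)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    d, p = lilliefors(x, dist="norm")
    return float(d), float(p)


# ---------------------------------------------------------------------------
# report tables

def _freq_table(labels_df: pd.DataFrame, by: List[str]) -> pd.DataFrame:
    rows = []
    for key, sub in labels_df.groupby(by, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        freq = pool_strategies(sub["category"])
        row = dict(zip(by, key))
        row.update(freq.counts.to_dict())
        row.update(freq.pooled.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(
    metrics: Optional[pd.DataFrame] = None,
    labels: Optional[pd.DataFrame] = None,
    by: Optional[List[str]] = None,
) -> Dict[str, pd.DataFrame]:
    """Build the summary report tables.

    ``metrics`` is a per-trial metrics table (numeric columns summarized as
    median and interquartile range per group); ``labels`` a per-trial table
    with a ``category`` column (strategy frequencies per group).  ``by``
    defaults to the grouping columns present among (group, day, trial_type).
    Empty inputs yield empty tables.
    """
    out: Dict[str, pd.DataFrame] = {}
    default_by = ("group", "day", "trial_type")

    if metrics is not None:
        cols = [c for c in (by or default_by) if c in metrics.columns]
        num = metrics.select_dtypes(include=[np.number]).columns.difference(cols)
        if len(metrics) and cols:
            agg = metrics.groupby(cols, dropna=False)[list(num)].describe(percentiles=[0.25, 0.5, 0.75])
            keep = [(c, s) for c in num for s in ("50%", "25%", "75%")]
            tidy = agg.loc[:, keep]
            tidy.columns = [f"{c}_{ {'50%': 'median', '25%': 'q1', '75%': 'q3'}[s] }" for c, s in keep]
            out["metrics"] = tidy.reset_index()
        else:
            out["metrics"] = pd.DataFrame()

    if labels is not None:
        cols = [c for c in (by or default_by) if c in labels.columns]
        if len(labels) and cols:
            out["strategy_frequencies"] = _freq_table(labels, cols)
        elif len(labels):
            freq = pool_strategies(labels["category"])
            out["strategy_frequencies"] = pd.DataFrame([{**freq.counts.to_dict(), **freq.pooled.to_dict()}])
        else:
            out["strategy_frequencies"] = pd.DataFrame()

    return out
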
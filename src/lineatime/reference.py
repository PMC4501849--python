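"""Multi-embryo wild-type reference: per-pair ADS distributions with
normality assessment, per-cell timing statistics, asynchronous-pair
selection, and normal-model tail probabilities.

The screen models each monitored pair's wild-type ADS as a normal
distribution fitted across the cohort; D'Agostino's K-squared omnibus test
records how defensible that is per pair, and pairs failing it are retained
but flagged so reports can caveat them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .timing import ads_table, cycle_lengths

__all__ = [
    "PairReference",
    "WTReference",
    "assign_pair_categories",
    "build_pair_reference",
    "dagostino_k2",
    "select_async_pairs",
    "tail_probability",
]

PAIR_CATEGORIES = ("different-fate", "same-fate", "blast-vs-terminal", "unassigned")


def dagostino_k2(sample) -> tuple[float, float]:
    """D'Agostino's K-squared omnibus normality test.

    Combines the normalized skewness and kurtosis statistics,
    K2 = z(skew)^2 + z(kurt)^2, referred to a chi-square with 2 df.
    Requires n >= 8 and nonzero variance.
    """
    x = np.asarray(sample, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError(f"K-squared test requires n >= 8, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("sample has zero variance")

    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    m3 = np.mean((x - m) ** 3)
    m4 = np.mean((x - m) ** 4)

    # skewness z (D'Agostino 1970 transformation)
    b1 = m3 / m2**1.5
    y = b1 * np.sqrt((n + 1.0) * (n + 3.0) / (6.0 * (n - 2.0)))
    beta2 = (
        3.0 * (n**2 + 27.0 * n - 70.0) * (n + 1.0) * (n + 3.0)
        / ((n - 2.0) * (n + 5.0) * (n + 7.0) * (n + 9.0))
    )
    w2 = -1.0 + np.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / np.sqrt(0.5 * np.log(w2))
    alpha = np.sqrt(2.0 / (w2 - 1.0))
    y = np.where(y == 0, 1.0, y)  # guard against log of 0 for exactly symmetric data
    z1 = delta * np.log(y / alpha + np.sqrt((y / alpha) ** 2 + 1.0))

    # kurtosis z (Anscombe & Glynn 1983 transformation)
    b2 = m4 / m2**2
    e_b2 = 3.0 * (n - 1.0) / (n + 1.0)
    var_b2 = 24.0 * n * (n - 2.0) * (n - 3.0) / ((n + 1.0) ** 2 * (n + 3.0) * (n + 5.0))
    xstat = (b2 - e_b2) / np.sqrt(var_b2)
    sqrtbeta1 = (
        6.0 * (n**2 - 5.0 * n + 2.0) / ((n + 7.0) * (n + 9.0))
        * np.sqrt(6.0 * (n + 3.0) * (n + 5.0) / (n * (n - 2.0) * (n - 3.0)))
    )
    a = 6.0 + 8.0 / sqrtbeta1 * (2.0 / sqrtbeta1 + np.sqrt(1.0 + 4.0 / sqrtbeta1**2))
    term = (1.0 - 2.0 / a) / (1.0 + xstat * np.sqrt(2.0 / (a - 4.0)))
    z2 = (1.0 - 2.0 / (9.0 * a) - np.sign(term) * np.abs(term) ** (1.0 / 3.0)) / np.sqrt(
        2.0 / (9.0 * a)
    )

    k2 = float(z1) ** 2 + float(z2) ** 2
    p = float(stats.chi2.sf(k2, df=2))
    return float(k2), p


def tail_probability(mean: float, sd: float, x: float, side: str = "two") -> float:
    """Normal-model tail probability of an observation *x*.

    ``side`` is ``lower``, ``upper`` or ``two`` (2 * min(lower, upper)).
    A zero SD degenerates to p = 1 if x equals the mean, else 0 (warned).
    """
    if side not in ("lower", "upper", "two"):
        raise ValueError(f"invalid side {side!r}")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        warnings.warn("degenerate reference (sd = 0)", stacklevel=2)
        return 1.0 if x == mean else 0.0
    z = (x - mean) / sd
    lower = float(stats.norm.cdf(z))
    upper = float(stats.norm.sf(z))
    if side == "lower":
        return lower
    if side == "upper":
        return upper
    return min(1.0, 2.0 * min(lower, upper))


@dataclass
class PairReference:
    """Wild-type ADS distribution of one sister pair."""

    parent: str
    daughters: tuple[str, str]
    n: int
    mean_ads_min: float
    sd_ads_min: float
    k2_stat: float
    k2_p: float
    normal_pass: bool
    category: str = "unassigned"


@dataclass
class WTReference:
    """Cohort-level wild-type model.

    ``pairs`` maps parent name -> :class:`PairReference`; ``cell_stats`` is a
    DataFrame (index cell) of per-cell cycle-length mean/SD/n; ``skipped``
    lists pairs excluded for insufficient uncensored embryos. Spatial
    references (position centroids, angle samples) are attached by the
    spatial module via ``spatial_refs``.
    """

    pairs: dict[str, PairReference]
    cell_stats: pd.DataFrame
    ads_wide: pd.DataFrame
    skipped: pd.DataFrame
    alpha: float = 0.05
    min_n: int = 8
    cohort_ids: tuple[str, ...] = ()
    monitored_pairs: tuple[str, ...] = ()
    spatial_refs: dict = field(default_factory=dict)

    def pair_table(self) -> pd.DataFrame:
        rows = [
            {
                "parent": p.parent,
                "daughter1": p.daughters[0],
                "daughter2": p.daughters[1],
                "n": p.n,
                "mean_ads_min": p.mean_ads_min,
                "sd_ads_min": p.sd_ads_min,
                "k2_stat": p.k2_stat,
                "k2_p": p.k2_p,
                "normal_pass": p.normal_pass,
                "category": p.category,
            }
            for p in self.pairs.values()
        ]
        return pd.DataFrame(rows).set_index("parent").sort_index()


def build_pair_reference(
    cohort_trees,
    alpha: float = 0.05,
    min_n: int = 8,
    cohort_ids=None,
) -> WTReference:
    """Build the wild-type reference from a cohort of lineage trees.

    For every parent with at least *min_n* uncensored ADS values across the
    cohort: mean, SD and the K-squared normality test. Non-normal pairs are
    retained but flagged. Per-cell cycle-length statistics are included.
    """
    trees = list(cohort_trees)
    if len(trees) < min_n:
        raise ValueError(f"cohort of {len(trees)} embryos < min_n = {min_n}")
    ids = tuple(cohort_ids) if cohort_ids is not None else tuple(range(len(trees)))

    ads_wide = pd.concat(
        [
            ads_table(t).loc[lambda d: ~d["censored"], "ads_min"].rename(i)
            for i, t in zip(ids, trees)
        ],
        axis=1,
    )
    cyc_wide = pd.concat(
        [
            cycle_lengths(t).loc[lambda d: ~d["censored"], "cycle_length_min"].rename(i)
            for i, t in zip(ids, trees)
        ],
        axis=1,
    )
    cell_stats = pd.DataFrame(
        {
            "n": cyc_wide.notna().sum(axis=1),
            "mean_min": cyc_wide.mean(axis=1),
            "sd_min": cyc_wide.std(axis=1, ddof=1),
        }
    )

    daughters = {}
    for t in trees:
        for parent in ads_wide.index:
            if parent in t and t[parent].daughters is not None:
                daughters[parent] = t[parent].daughters
        if len(daughters) == len(ads_wide):
            break

    pairs: dict[str, PairReference] = {}
    skipped_rows = []
    for parent, row in ads_wide.iterrows():
        vals = row.dropna().to_numpy(dtype=float)
        if len(vals) < min_n:
            skipped_rows.append({"parent": parent, "n": len(vals), "min_n": min_n})
            continue
        k2, p = dagostino_k2(vals) if np.ptp(vals) > 0 else (np.nan, np.nan)
        pairs[parent] = PairReference(
            parent=parent,
            daughters=tuple(daughters.get(parent, ("", ""))),
            n=len(vals),
            mean_ads_min=float(vals.mean()),
            sd_ads_min=float(vals.std(ddof=1)),
            k2_stat=k2,
            k2_p=p,
            normal_pass=bool(p > alpha) if np.isfinite(p) else False,
        )

    return WTReference(
        pairs=pairs,
        cell_stats=cell_stats,
        ads_wide=ads_wide,
        skipped=pd.DataFrame(skipped_rows, columns=["parent", "n", "min_n"]),
        alpha=alpha,
        min_n=min_n,
        cohort_ids=ids,
    )


def select_async_pairs(ref: WTReference, threshold_min: float = 5.0) -> list[str]:
    """Pairs with mean wild-type ADS strictly greater than the threshold.

    These become the monitored pairs of the screen (the reference is updated
    in place as well).
    """
    chosen = sorted(
        p.parent for p in ref.pairs.values() if p.mean_ads_min > threshold_min
    )
    ref.monitored_pairs = tuple(chosen)
    return chosen


def assign_pair_categories(ref: WTReference, annotation) -> WTReference:
    """Attach fate categories (different-fate / same-fate / blast-vs-terminal)
    from a parent -> category mapping; unannotated pairs stay unassigned."""
    items = annotation.items() if hasattr(annotation, "items") else annotation
    for parent, category in items:
        if category not in PAIR_CATEGORIES:
            raise ValueError(f"unknown category {category!r} for {parent}")
        if parent not in ref.pairs:
            warnings.warn(f"annotation names unknown pair parent {parent!r}", stacklevel=2)
            continue
        ref.pairs[parent].category = category
    return ref
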
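"""Cell-cycle lengths, division asynchrony between sisters, and cohort
reproducibility summaries.

The cycle length of a cell is the time from its birth (appearance after its
mother's division) to its own division, in minutes. The asynchrony of
division between sister cells (ADS) of a parent is the absolute difference
between its two daughters' cycle lengths — equivalently, between their
division times, since sisters are born at the same frame.

Censoring follows the study design: cells that had not divided by the
analysis cutoff, cells that died, cells not observed from birth, and the
first two rounds of division (AB, P1, ABa, ABp, EMS, P2 — imaging starts at
the two-to-four-cell stage, so their timings are unreliable) carry a censor
reason instead of a length.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from . import nomenclature as nom
from .model import LineageTree

__all__ = [
    "ads_table",
    "analysis_cutoff_frame",
    "cluster_embryos",
    "compute_ads",
    "correlation_matrix",
    "cycle_lengths",
    "generation_sd_profile",
]

CENSOR_REASONS = (
    "early-round-excluded",
    "not-observed-from-birth",
    "dead",
    "undivided-at-cutoff",
)


def analysis_cutoff_frame(tree: LineageTree, cell_target: int = 350) -> int:
    """Frame at which the embryo first reaches *cell_target* cells, or the
    last curated frame if it never does."""
    events = []
    for node in tree:
        events.append((node.birth_frame, +1))
        events.append((node.last_frame + 1, -1))
    events.sort()
    count = 0
    for frame, delta in events:
        count += delta
        if count >= cell_target:
            return min(frame, tree.last_curated_frame)
    return tree.last_curated_frame


def cycle_lengths(
    tree: LineageTree,
    frame_interval_min: float | None = None,
    cutoff_frame: int | None = None,
) -> pd.DataFrame:
    """Per-cell cycle lengths with censoring flags.

    Returns a DataFrame indexed by cell name with columns ``founder``,
    ``generation``, ``cycle_length_min`` (NaN when censored), ``censored``
    and ``reason``.
    """
    dt = frame_interval_min if frame_interval_min is not None else tree.frame_interval_min
    cutoff = cutoff_frame if cutoff_frame is not None else tree.last_curated_frame
    if cutoff > tree.last_curated_frame:
        raise ValueError("cutoff_frame beyond last curated frame")

    rows = []
    roots = set(tree.roots)
    for node in sorted(tree, key=lambda n: nom.sort_key(n.name)):
        length = np.nan
        reason = None
        div = tree.division_frame(node.name)
        if node.name in nom.EARLY_ROUND_CELLS:
            reason = "early-round-excluded"
        elif node.name in roots:
            reason = "not-observed-from-birth"
        elif node.died:
            reason = "dead"
        elif div is None or div > cutoff:
            reason = "undivided-at-cutoff"
        else:
            length = (div - node.birth_frame) * dt
        rows.append(
            {
                "cell": node.name,
                "founder": node.founder,
                "generation": node.generation,
                "cycle_length_min": length,
                "censored": reason is not None,
                "reason": reason,
            }
        )
    return pd.DataFrame(rows).set_index("cell")


def compute_ads(
    tree: LineageTree,
    parent: str,
    frame_interval_min: float | None = None,
    cutoff_frame: int | None = None,
) -> dict:
    """ADS of one parent's sister pair, in minutes.

    Returns a mapping with ``parent``, ``daughters``, ``ads_min`` (NaN when
    censored), ``signed_ads_min`` (first daughter in lineal order minus the
    second) and ``censored``.
    """
    dt = frame_interval_min if frame_interval_min is not None else tree.frame_interval_min
    cutoff = cutoff_frame if cutoff_frame is not None else tree.last_curated_frame
    node = tree[parent]
    if node.daughters is None:
        raise ValueError(f"{parent} did not divide; ADS undefined")
    d1, d2 = node.daughters
    divs = [tree.division_frame(d) for d in (d1, d2)]
    dead = any(tree[d].died for d in (d1, d2))
    if dead or any(dv is None or dv > cutoff for dv in divs):
        return {
            "parent": parent,
            "daughters": (d1, d2),
            "ads_min": np.nan,
            "signed_ads_min": np.nan,
            "censored": True,
        }
    signed = (divs[0] - divs[1]) * dt
    return {
        "parent": parent,
        "daughters": (d1, d2),
        "ads_min": abs(signed),
        "signed_ads_min": signed,
        "censored": False,
    }


def ads_table(
    tree: LineageTree,
    frame_interval_min: float | None = None,
    cutoff_frame: int | None = None,
) -> pd.DataFrame:
    """ADS for every divided parent, indexed by parent name.

    Pairs whose parent belongs to the first two division rounds are censored
    (reason ``early-round-excluded``): the screen never monitors them.
    """
    rows = []
    for node in sorted(tree, key=lambda n: nom.sort_key(n.name)):
        if node.daughters is None:
            continue
        rec = compute_ads(tree, node.name, frame_interval_min, cutoff_frame)
        if node.name in ({"AB", "P1"} | nom.EARLY_ROUND_CELLS):
            rec.update(ads_min=np.nan, signed_ads_min=np.nan, censored=True)
            rec["reason"] = "early-round-excluded"
        else:
            rec["reason"] = "censored-daughter" if rec["censored"] else None
        rows.append(rec)
    df = pd.DataFrame(rows)
    df[["daughter1", "daughter2"]] = pd.DataFrame(
        df.pop("daughters").tolist(), index=df.index
    )
    return df.set_index("parent")


def _uncensored_series(table: pd.DataFrame) -> pd.Series:
    return table.loc[~table["censored"], "cycle_length_min"]


def correlation_matrix(cohort: list[pd.DataFrame], min_shared: int = 3) -> pd.DataFrame:
    """Pairwise Pearson r of cycle lengths between embryos.

    Entry (i, j) is computed over the cells uncensored in both embryos;
    entries with fewer than *min_shared* shared cells are NaN.
    """
    if len(cohort) < 2:
        raise ValueError("need at least two embryos")
    series = [_uncensored_series(t) for t in cohort]
    n = len(series)
    out = np.full((n, n), np.nan)
    np.fill_diagonal(out, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            joined = pd.concat([series[i], series[j]], axis=1, join="inner")
            if len(joined) < min_shared:
                continue
            r = np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1]
            out[i, j] = out[j, i] = r
    return pd.DataFrame(out)


def cluster_embryos(matrix: pd.DataFrame) -> dict:
    """Complete-linkage clustering of embryos on Manhattan distances between
    their rows of the correlation matrix.

    Missing entries are imputed by the row mean (and reported). Returns
    ``{"linkage": Z, "leaf_order": [...], "imputed": n}``.
    """
    m = matrix.to_numpy(dtype=float).copy()
    if m.shape[0] < 2:
        raise ValueError("need at least two rows to cluster")
    imputed = int(np.isnan(m).sum())
    if imputed:
        row_means = np.nanmean(m, axis=1)
        idx = np.where(np.isnan(m))
        m[idx] = row_means[idx[0]]
    z = linkage(pdist(m, metric="cityblock"), method="complete")
    return {"linkage": z, "leaf_order": leaves_list(z).tolist(), "imputed": imputed}


def generation_sd_profile(cohort: list[pd.DataFrame], min_n: int = 3) -> pd.DataFrame:
    """Across-embryo SD of each cell's cycle length, summarized by generation.

    Cells uncensored in at least *min_n* embryos contribute; the summary is
    the mean per-cell SD and contributing cell count per generation.
    """
    if len(cohort) < min_n:
        raise ValueError(f"need at least {min_n} embryos")
    wide = pd.concat(
        [_uncensored_series(t).rename(i) for i, t in enumerate(cohort)], axis=1
    )
    counts = wide.notna().sum(axis=1)
    wide = wide[counts >= min_n]
    sds = wide.std(axis=1, ddof=1)
    gens = pd.Series({c: nom.generation_of(c) for c in wide.index})
    out = pd.DataFrame({"generation": gens, "sd_min": sds})
    return (
        out.groupby("generation")["sd_min"]
        .agg(mean_sd_min="mean", n_cells="count")
        .reset_index()
    )
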
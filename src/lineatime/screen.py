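"""RNAi-screen statistics: embryo QC, ADS-reduction hit calling with the
two-replicate rule, variance-buffering detection, and tissue-marker
expression comparison.

A gene is called a hit for a monitored sister pair when, in at least
``min_replicates`` QC-passing replicate embryos, the pair's ADS is reduced
by at least the reduction fraction relative to the wild-type mean, lies
below that mean, and falls in the tail of the wild-type normal model at the
requested significance level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import nomenclature as nom
from .model import EmbryoRecording, build_lineage, cell_count_at
from .reference import WTReference, tail_probability
from .timing import ads_table, analysis_cutoff_frame, cycle_lengths

__all__ = [
    "GeneScreenResult",
    "QCResult",
    "buffering_test",
    "call_hits",
    "expression_change",
    "qc_embryo",
    "screen_gene",
    "speed_curve",
]


@dataclass
class QCResult:
    recording_id: str
    passed: bool
    reasons: tuple[str, ...] = ()
    cells_at_last_frame: int = 0
    max_cells_by_240: int | None = None


def qc_embryo(
    recording: EmbryoRecording,
    min_cells_last: int = 300,
    min_cells_by_frame: int = 350,
    qc_frame: int = 240,
) -> QCResult:
    """Developmental-speed QC.

    Fails an embryo that has fewer than 300 cells at its last editable
    frame; if the recording extends to frame 240, it must additionally have
    reached 350 cells by then. Recordings that end before frame 240 are
    judged by the first clause alone.
    """
    obs = recording.observations
    if not len(obs):
        raise ValueError(f"{recording.id}: empty recording")
    reasons = []
    last = recording.last_curated_frame
    n_last = cell_count_at(recording, last)
    if n_last < min_cells_last:
        reasons.append("under-300-at-last-editable")
    max_by_240 = None
    if last >= qc_frame:
        counts = obs.loc[obs["frame"] <= qc_frame, "frame"].value_counts()
        max_by_240 = int(counts.max()) if len(counts) else 0
        if max_by_240 < min_cells_by_frame:
            reasons.append("under-350-at-frame-240")
    return QCResult(
        recording_id=recording.id,
        passed=not reasons,
        reasons=tuple(reasons),
        cells_at_last_frame=n_last,
        max_cells_by_240=max_by_240,
    )


@dataclass
class GeneScreenResult:
    """Per gene screen outcome across the monitored sister pairs."""

    gene: str
    status: str  # "screened" | "unscreenable"
    n_replicates: int
    replicate_table: pd.DataFrame  # one row per (replicate, pair)
    hit_levels: dict[str, float | None]  # parent -> 0.01 / 0.05 / None
    excluded_replicates: tuple[str, ...] = ()
    buffering: pd.DataFrame | None = None
    buffering_flag: bool | None = None
    expression: dict = field(default_factory=dict)

    def hit_pairs(self, level: float = 0.05) -> list[str]:
        return sorted(
            p for p, lv in self.hit_levels.items() if lv is not None and lv <= level
        )


def call_hits(
    gene: str,
    replicate_ads: list[dict],
    ref: WTReference,
    pairs=None,
    reduction: float = 0.5,
    alphas: tuple[float, float] = (0.05, 0.01),
    min_replicates: int = 2,
    side: str = "two",
) -> GeneScreenResult:
    """Call ADS-reduction hits for one gene.

    ``replicate_ads`` holds one mapping per QC-passing replicate embryo:
    parent name -> ADS in minutes (NaN / missing = censored). For each
    replicate and monitored pair the flag at level alpha requires an
    uncensored ADS that is (i) at most (1 - reduction) times the wild-type
    mean, (ii) below the wild-type mean, and (iii) in the tail of the
    wild-type normal model with p < alpha. A pair's hit level is the
    strictest alpha at which at least ``min_replicates`` replicates flag.
    """
    pairs = list(pairs) if pairs is not None else list(ref.monitored_pairs)
    alphas = tuple(sorted(alphas, reverse=True))  # loose first (0.05, 0.01)
    if not replicate_ads:
        return GeneScreenResult(
            gene=gene,
            status="unscreenable",
            n_replicates=0,
            replicate_table=pd.DataFrame(),
            hit_levels={p: None for p in pairs},
        )

    rows = []
    for r, ads in enumerate(replicate_ads):
        for parent in pairs:
            pref = ref.pairs.get(parent)
            value = ads.get(parent)
            value = np.nan if value is None else float(value)
            row = {
                "replicate": r,
                "parent": parent,
                "ads_min": value,
                "wt_mean": pref.mean_ads_min if pref else np.nan,
                "reduction_frac": np.nan,
                "p": np.nan,
            }
            for a in alphas:
                row[f"flag{a:g}"] = False
            if pref is not None and np.isfinite(value):
                row["reduction_frac"] = 1.0 - value / pref.mean_ads_min
                p = tail_probability(pref.mean_ads_min, pref.sd_ads_min, value, side)
                row["p"] = p
                directional = (
                    value <= (1.0 - reduction) * pref.mean_ads_min
                    and value < pref.mean_ads_min
                )
                for a in alphas:
                    row[f"flag{a:g}"] = bool(directional and p < a)
            rows.append(row)
    table = pd.DataFrame(rows)

    hit_levels: dict[str, float | None] = {}
    for parent in pairs:
        sub = table[table["parent"] == parent]
        level = None
        for a in alphas:  # 0.05 first, overwritten by 0.01 if it also holds
            if int(sub[f"flag{a:g}"].sum()) >= min_replicates:
                level = a
        hit_levels[parent] = level

    return GeneScreenResult(
        gene=gene,
        status="screened",
        n_replicates=len(replicate_ads),
        replicate_table=table,
        hit_levels=hit_levels,
    )


def screen_gene(
    gene: str,
    recordings: list[EmbryoRecording],
    ref: WTReference,
    cell_target: int = 350,
    **hit_kwargs,
) -> GeneScreenResult:
    """QC the replicates of one gene, extract their ADS values and call hits."""
    passing, excluded = [], []
    for rec in recordings:
        qc = qc_embryo(rec)
        (passing if qc.passed else excluded).append(rec)
    replicate_ads = []
    for rec in passing:
        tree = build_lineage(rec)
        cutoff = analysis_cutoff_frame(tree, cell_target)
        tab = ads_table(tree, cutoff_frame=cutoff)
        replicate_ads.append(tab.loc[~tab["censored"], "ads_min"].to_dict())
    result = call_hits(gene, replicate_ads, ref, **hit_kwargs)
    result.excluded_replicates = tuple(r.id for r in excluded)
    if not passing:
        result.status = "unscreenable"
    return result


def buffering_test(
    perturbed_tables: list[pd.DataFrame],
    wildtype_tables: list[pd.DataFrame],
    lineage: str = "AB",
    alpha: float = 0.01,
    min_deviations: int = 3,
    min_wt_embryos: int = 3,
    absolute: bool = False,
    center: bool = True,
) -> tuple[pd.DataFrame, bool]:
    """Variance-buffering (capacitor) detection by a one-sided F-test.

    For each generation of the chosen sublineage, deviations of each
    embryo's cycle lengths from the wild-type per-cell mean are pooled and
    the perturbed-vs-wild-type variance ratio is referred to an F
    distribution (one-sided: inflation only). With ``center`` (default) each
    embryo's mean deviation within the generation is removed first, so a
    shared per-embryo pace offset does not masquerade as dispersion; the
    degrees of freedom drop by one per embryo. ``absolute`` runs the test on
    absolute deviations instead of signed ones.

    Deviations are standardized for the finite wild-type cohort: a cell
    whose mean rests on n embryos contributes a perturbed deviation with
    variance sigma^2 (1 + 1/n) but a (self-included) wild-type deviation
    with variance sigma^2 (1 - 1/n); both are rescaled to sigma^2, and cells
    supported by fewer than ``min_wt_embryos`` wild-type embryos are
    dropped, so the variance ratio is F-calibrated even for small cohorts.

    Returns (per-generation table, flag), flag = min p < alpha.
    """
    if len(wildtype_tables) < 2:
        raise ValueError("need at least two wild-type embryos")
    if not perturbed_tables:
        raise ValueError("need at least one perturbed embryo")

    def lineage_cells(tab: pd.DataFrame) -> pd.DataFrame:
        sel = ~tab["censored"] & tab.index.map(lambda c: nom.is_ancestor(lineage, c))
        return tab.loc[sel, ["generation", "cycle_length_min"]]

    wt = [lineage_cells(t) for t in wildtype_tables]
    pt = [lineage_cells(t) for t in perturbed_tables]
    wt_wide = pd.concat([t["cycle_length_min"] for t in wt], axis=1)
    wt_n = wt_wide.notna().sum(axis=1)
    keep = wt_n >= max(min_wt_embryos, 2)
    wt_mean = wt_wide.mean(axis=1)[keep]
    wt_n = wt_n[keep]

    def deviations(tables, wildtype_side: bool):
        """per generation: list of per-embryo standardized deviation arrays."""
        sign = -1.0 if wildtype_side else 1.0
        scale = np.sqrt(1.0 + sign / wt_n)
        pools: dict[int, list[np.ndarray]] = {}
        for t in tables:
            d = (t["cycle_length_min"] - wt_mean.reindex(t.index)) / scale.reindex(
                t.index
            )
            d = d.dropna()
            gens = t.loc[d.index, "generation"]
            for g, vals in d.groupby(gens):
                pools.setdefault(int(g), []).append(vals.to_numpy())
        return pools

    def pooled_var(chunks):
        if center:
            centered = [c - c.mean() for c in chunks]
            vals = np.concatenate(centered)
            df = len(vals) - len(chunks)
        else:
            vals = np.concatenate(chunks)
            df = len(vals) - 1
            vals = vals - vals.mean()
        if df < 1:
            return np.nan, 0
        return float(np.sum(vals**2) / df), df

    wt_pools = deviations(wt, wildtype_side=True)
    pt_pools = deviations(pt, wildtype_side=False)
    rows = []
    for g in sorted(set(wt_pools) & set(pt_pools)):
        wchunks = [np.abs(c) if absolute else c for c in wt_pools[g]]
        pchunks = [np.abs(c) if absolute else c for c in pt_pools[g]]
        n_w = sum(len(c) for c in wchunks)
        n_p = sum(len(c) for c in pchunks)
        if n_w < min_deviations or n_p < min_deviations:
            rows.append(
                {"generation": g, "n_perturbed": n_p, "n_wildtype": n_w,
                 "f_stat": np.nan, "p": np.nan, "skipped": True}
            )
            continue
        var_p, df_p = pooled_var(pchunks)
        var_w, df_w = pooled_var(wchunks)
        if not (df_p >= 1 and df_w >= 1 and var_w > 0):
            rows.append(
                {"generation": g, "n_perturbed": n_p, "n_wildtype": n_w,
                 "f_stat": np.nan, "p": np.nan, "skipped": True}
            )
            continue
        f = var_p / var_w
        p = float(stats.f.sf(f, df_p, df_w))
        rows.append(
            {"generation": g, "n_perturbed": n_p, "n_wildtype": n_w,
             "f_stat": f, "p": p, "skipped": False}
        )
    table = pd.DataFrame(
        rows,
        columns=["generation", "n_perturbed", "n_wildtype", "f_stat", "p", "skipped"],
    )
    valid = table["p"].dropna()
    flag = bool(len(valid) and valid.min() < alpha)
    return table, flag


def expression_change(
    perturbed: EmbryoRecording,
    wildtype_cohort: list[EmbryoRecording],
    sublineage_root: str,
    loss_ratio: float = 0.2,
    reduced_ratio: float = 0.67,
    gained_ratio: float = 1.5,
) -> dict:
    """Mean tissue-marker intensity in a sublineage, perturbed vs wild type.

    ratio = mean intensity over all observations of the sublineage's cells
    in the perturbed embryo divided by the same quantity averaged across the
    wild-type cohort. Calls: lost < 0.2 <= reduced < 0.67 <= unchanged
    <= 1.5 < gained.
    """
    def sub_mean(rec: EmbryoRecording) -> float:
        obs = rec.observations
        if obs["intensity"].isna().all():
            raise ValueError(f"{rec.id}: recording has no intensity values")
        cells = [c for c in obs["cell"].unique() if nom.is_ancestor(sublineage_root, c)]
        sel = obs.loc[obs["cell"].isin(cells), "intensity"].dropna()
        if not len(sel):
            return np.nan
        return float(sel.mean())

    wt_means = [sub_mean(r) for r in wildtype_cohort]
    wt_level = float(np.nanmean(wt_means))
    pert_level = sub_mean(perturbed)
    caveat = None
    if np.isnan(pert_level):
        # sublineage never appeared (e.g. arrest) — fall back to whole embryo
        pert_level = float(perturbed.observations["intensity"].dropna().mean())
        caveat = "sublineage-absent"
    ratio = pert_level / wt_level
    if ratio < loss_ratio:
        call = "lost"
    elif ratio < reduced_ratio:
        call = "reduced"
    elif ratio <= gained_ratio:
        call = "unchanged"
    else:
        call = "gained"
    return {"ratio": float(ratio), "call": call, "caveat": caveat}


def speed_curve(recording: EmbryoRecording) -> pd.DataFrame:
    """Total cell count over time: one row per frame up to the last curated
    frame, columns frame, time_min, cell_count."""
    obs = recording.observations
    counts = obs["frame"].value_counts().sort_index()
    frames = np.arange(int(obs["frame"].min()), recording.last_curated_frame + 1)
    series = counts.reindex(frames, fill_value=0)
    return pd.DataFrame(
        {
            "frame": frames,
            "time_min": frames * recording.frame_interval_min,
            "cell_count": series.to_numpy(),
        }
    )
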
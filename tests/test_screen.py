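import numpy as np
import pandas as pd
import pytest

from lineatime.model import build_lineage
from lineatime.reference import PairReference, WTReference
from lineatime.screen import (
    buffering_test,
    call_hits,
    expression_change,
    qc_embryo,
    screen_gene,
    speed_curve,
)
from lineatime.simulate import (
    NoiseModel,
    PerturbationSpec,
    make_template,
    simulate_cohort,
    simulate_embryo,
)
from lineatime.timing import cycle_lengths


def make_ref(mean=10.0, sd=1.0, parent="ABala"):
    return WTReference(
        pairs={parent: PairReference(parent, ("d1", "d2"), 91, mean, sd, 0.0, 0.5, True)},
        cell_stats=pd.DataFrame(),
        ads_wide=pd.DataFrame(),
        skipped=pd.DataFrame(),
        monitored_pairs=(parent,),
    )


class TestQC:
    def test_wildtype_passes(self, wt_embryo):
        assert qc_embryo(wt_embryo).passed

    def test_under_300_at_last_frame_fails(self, template):
        rec = simulate_embryo(
            template, seed=8, perturbation=PerturbationSpec(arrest_frame=80)
        )
        qc = qc_embryo(rec)
        assert not qc.passed
        assert "under-300-at-last-editable" in qc.reasons

    def test_slow_embryo_fails_350_by_240_clause(self, template):
        rec = simulate_embryo(
            template, seed=8, perturbation=PerturbationSpec(slowdown=1.6)
        )
        qc = qc_embryo(rec)
        if rec.last_curated_frame >= 240:
            assert "under-350-at-frame-240" in qc.reasons or qc.passed is False

    def test_short_recording_judged_by_first_clause_only(self, wt_embryo):
        qc = qc_embryo(wt_embryo)
        assert qc.max_cells_by_240 is None  # curation ended before frame 240


class TestCallHits:
    def test_strong_reduction_is_001_hit(self):
        # WT pair N(10, 1): 4.0 and 4.5 give 60%/55% reductions at z = -6/-5.5
        res = call_hits("g", [{"ABala": 4.0}, {"ABala": 4.5}, {"ABala": 9.0}], make_ref())
        assert res.hit_levels["ABala"] == 0.01

    def test_significant_but_small_reduction_is_not_hit(self):
        # 6.0 has p < 0.01 but only a 40% reduction -> no flags at all
        res = call_hits("g", [{"ABala": 6.0}, {"ABala": 9.0}, {"ABala": 9.0}], make_ref())
        assert res.hit_levels["ABala"] is None
        assert not res.replicate_table["flag0.05"].any()

    def test_single_flagged_replicate_insufficient(self):
        res = call_hits("g", [{"ABala": 4.0}, {"ABala": 9.5}], make_ref())
        assert res.hit_levels["ABala"] is None

    def test_replicate_order_invariance(self):
        reps = [{"ABala": 4.0}, {"ABala": 9.0}, {"ABala": 4.5}]
        a = call_hits("g", reps, make_ref()).hit_levels
        b = call_hits("g", list(reversed(reps)), make_ref()).hit_levels
        assert a == b

    def test_removing_unflagged_replicate_never_upgrades(self):
        reps = [{"ABala": 4.0}, {"ABala": 4.8}, {"ABala": 9.0}]
        full = call_hits("g", reps, make_ref()).hit_levels["ABala"]
        drop = call_hits("g", reps[:2], make_ref()).hit_levels["ABala"]
        assert (drop or 1.0) >= (full or 1.0)

    def test_censored_ads_cannot_flag(self):
        res = call_hits("g", [{"ABala": np.nan}, {}], make_ref())
        assert res.hit_levels["ABala"] is None

    def test_zero_replicates_unscreenable(self):
        res = call_hits("g", [], make_ref())
        assert res.status == "unscreenable"

    def test_001_hits_subset_of_005(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            reps = [{"ABala": float(rng.normal(6, 3))} for _ in range(3)]
            res = call_hits("g", reps, make_ref())
            t = res.replicate_table
            assert (t["flag0.01"] <= t["flag0.05"]).all()

    def test_null_hit_rate_is_low(self):
        # replicates drawn from the wild-type model itself almost never hit
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(500):
            reps = [{"ABala": float(rng.normal(10, 2))} for _ in range(3)]
            if call_hits("g", reps, make_ref(sd=2.0)).hit_levels["ABala"] is not None:
                hits += 1
        assert hits / 500 < 0.01


class TestScreenGene:
    def test_end_to_end_detection(self, template, wt_trees):
        from lineatime.reference import build_pair_reference, select_async_pairs

        ref = build_pair_reference(wt_trees)
        select_async_pairs(ref)
        reps = simulate_cohort(
            template, n=3, seed=77, id_prefix="p",
            perturbation=PerturbationSpec(ads_factor={"P3": 0.2}),
            target_gene="gene-x",
        )
        res = screen_gene("gene-x", reps, ref)
        assert res.hit_levels["P3"] == 0.01
        others = [p for p in ref.monitored_pairs if p != "P3"]
        assert all(res.hit_levels[p] is None for p in others)

    def test_all_replicates_failing_qc_is_unscreenable(self, template, wt_trees):
        from lineatime.reference import build_pair_reference, select_async_pairs

        ref = build_pair_reference(wt_trees)
        select_async_pairs(ref)
        reps = simulate_cohort(
            template, n=2, seed=78, id_prefix="a",
            perturbation=PerturbationSpec(arrest_frame=70), target_gene="gene-y",
        )
        res = screen_gene("gene-y", reps, ref)
        assert res.status == "unscreenable"
        assert len(res.excluded_replicates) == 2


class TestBuffering:
    def test_variance_inflation_flagged(self, template, wt_cycle_tables):
        pert = simulate_cohort(
            template, n=3, seed=99, id_prefix="p",
            perturbation=PerturbationSpec(variance_inflation={"AB": 4.0}),
        )
        tabs = [cycle_lengths(build_lineage(r)) for r in pert]
        table, flag = buffering_test(tabs, wt_cycle_tables)
        assert flag
        assert table["p"].min() < 1e-6

    def test_null_not_flagged_typically(self, template, wt_cycle_tables):
        flags = 0
        for seed in (301, 302, 303, 304, 305):
            pert = simulate_cohort(template, n=3, seed=seed, id_prefix="n")
            tabs = [cycle_lengths(build_lineage(r)) for r in pert]
            flags += buffering_test(tabs, wt_cycle_tables)[1]
        assert flags <= 1

    def test_small_generation_skipped(self):
        def tab(cells, gen, values):
            return pd.DataFrame(
                {"generation": gen, "cycle_length_min": values, "censored": False},
                index=pd.Index(cells, name="cell"),
            )

        wt = [tab(["ABal", "ABar"], 3, [20.0 + i, 21.0 + i]) for i in range(4)]
        pert = [tab(["ABal", "ABar"], 3, [20.0, 25.0])]
        table, flag = buffering_test(pert, wt, min_deviations=5)
        assert table["skipped"].all()
        assert not flag

    def test_absolute_mode_runs(self, wt_cycle_tables):
        table, _ = buffering_test(
            wt_cycle_tables[:2], wt_cycle_tables[2:], absolute=True
        )
        assert (table.loc[~table["skipped"], "p"] > 0).all()


class TestExpression:
    def test_knockout_is_lost(self, template, wt_cohort):
        ko = simulate_embryo(
            template, seed=5, perturbation=PerturbationSpec(expression_knockout="E")
        )
        out = expression_change(ko, wt_cohort, "E")
        assert out["call"] == "lost"
        assert out["ratio"] < 0.2

    def test_identical_recording_unchanged(self, wt_cohort):
        out = expression_change(wt_cohort[0], [wt_cohort[0]], "E")
        assert out["ratio"] == pytest.approx(1.0)
        assert out["call"] == "unchanged"

    def test_halved_intensity_reduced(self, wt_cohort):
        half = wt_cohort[0].with_observations(
            wt_cohort[0].observations.assign(
                intensity=wt_cohort[0].observations["intensity"] * 0.5
            )
        )
        out = expression_change(half, wt_cohort, "E")
        assert out["call"] == "reduced"

    def test_missing_intensity_is_error(self, make_toy, wt_cohort):
        rec = make_toy([("ABa", 1, 0, 0, 0)])
        with pytest.raises(ValueError, match="no intensity"):
            expression_change(rec, wt_cohort, "E")


class TestSpeedCurve:
    def test_four_cell_point(self, wt_embryo):
        from lineatime.spatial import last_four_cell_frame

        curve = speed_curve(wt_embryo).set_index("frame")
        assert curve.loc[last_four_cell_frame(wt_embryo), "cell_count"] == 4

    def test_monotone_and_endpoint(self, wt_embryo):
        from lineatime.model import cell_count_at

        curve = speed_curve(wt_embryo)
        assert (np.diff(curve["cell_count"]) >= 0).all()
        assert curve["cell_count"].iloc[-1] == cell_count_at(
            wt_embryo, wt_embryo.last_curated_frame
        )

    def test_slowdown_reaches_counts_later(self, template):
        fast = simulate_embryo(template, seed=31)
        slow = simulate_embryo(
            template, seed=31, perturbation=PerturbationSpec(slowdown=1.3)
        )
        for target in (50, 100, 200):
            f = speed_curve(fast).query("cell_count >= @target")["frame"].min()
            s = speed_curve(slow).query("cell_count >= @target")["frame"].min()
            assert s > f
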
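import numpy as np
import pandas as pd
import pytest

from lineatime.model import build_lineage
from lineatime.simulate import NoiseModel, make_template, simulate_cohort
from lineatime.timing import (
    ads_table,
    analysis_cutoff_frame,
    cluster_embryos,
    compute_ads,
    correlation_matrix,
    cycle_lengths,
    generation_sd_profile,
)


def chain_recording(make_toy, spans):
    """Recording from {cell: (birth, last)} frame spans."""
    rows = []
    for cell, (b, l) in spans.items():
        rows += [(cell, f, 0, 0, 0) for f in range(b, l + 1)]
    return make_toy(rows)


class TestCycleLengths:
    def test_basic_arithmetic(self, make_toy):
        rec = chain_recording(
            make_toy,
            {"ABa": (1, 39), "ABal": (40, 79), "ABar": (40, 100),
             "ABala": (80, 100), "ABalp": (80, 100)},
        )
        tab = cycle_lengths(build_lineage(rec))
        # born frame 40, daughters appear frame 80, dt = 1.5 -> 60 min
        assert tab.loc["ABal", "cycle_length_min"] == pytest.approx(60.0)

    def test_early_rounds_always_censored(self, wt_tree):
        tab = cycle_lengths(wt_tree)
        for cell in ("AB", "P1", "ABa", "ABp", "EMS", "P2"):
            assert tab.loc[cell, "reason"] == "early-round-excluded"

    def test_undivided_at_cutoff(self, make_toy):
        rec = chain_recording(make_toy, {"ABa": (1, 5), "ABal": (6, 20), "ABar": (6, 20)})
        tab = cycle_lengths(build_lineage(rec))
        assert tab.loc["ABal", "reason"] == "undivided-at-cutoff"

    def test_division_after_cutoff_censored(self, make_toy):
        rec = chain_recording(
            make_toy,
            {"ABa": (1, 5), "ABal": (6, 10), "ABar": (6, 20),
             "ABala": (11, 20), "ABalp": (11, 20)},
        )
        tab = cycle_lengths(build_lineage(rec), cutoff_frame=10)
        assert tab.loc["ABal", "reason"] == "undivided-at-cutoff"

    def test_dead_cell_censored(self, make_toy):
        rec = make_toy(
            [("ABa", 1, 0, 0, 0), ("ABa", 2, 0, 0, 0), ("ABp", 1, 0, 0, 0),
             ("ABpa", 2, 0, 0, 0), ("ABpp", 2, 0, 0, 0)],
            death_cells=("ABpa",),
        )
        tab = cycle_lengths(build_lineage(rec))
        assert tab.loc["ABpa", "reason"] == "dead"

    def test_all_lengths_are_frame_multiples(self, wt_tree):
        tab = cycle_lengths(wt_tree)
        vals = tab["cycle_length_min"].dropna()
        assert len(vals) > 100
        assert np.allclose(np.mod(vals, 1.5), 0)


class TestADS:
    def test_arithmetic_and_symmetry(self, make_toy):
        rec = chain_recording(
            make_toy,
            {"ABa": (1, 39), "ABal": (40, 99), "ABar": (40, 109),
             "ABala": (100, 115), "ABalp": (100, 115),
             "ABara": (110, 115), "ABarp": (110, 115)},
        )
        tree = build_lineage(rec)
        m = compute_ads(tree, "ABa")
        # daughters divide at frames 100 and 110 -> 15 min
        assert m["ads_min"] == pytest.approx(15.0)
        assert m["ads_min"] == pytest.approx(abs(m["signed_ads_min"]))

    def test_identical_division_frames_give_zero(self, make_toy):
        rec = chain_recording(
            make_toy,
            {"ABa": (1, 9), "ABal": (10, 19), "ABar": (10, 19),
             "ABala": (20, 25), "ABalp": (20, 25),
             "ABara": (20, 25), "ABarp": (20, 25)},
        )
        assert compute_ads(build_lineage(rec), "ABa")["ads_min"] == 0.0

    def test_undivided_parent_is_error(self, make_toy):
        rec = make_toy([("ABa", 1, 0, 0, 0)])
        with pytest.raises(ValueError, match="did not divide"):
            compute_ads(build_lineage(rec), "ABa")

    def test_censored_daughter_censors_pair(self, make_toy):
        rec = chain_recording(
            make_toy,
            {"ABa": (1, 9), "ABal": (10, 19), "ABar": (10, 30),
             "ABala": (20, 30), "ABalp": (20, 30)},
        )
        assert compute_ads(build_lineage(rec), "ABa")["censored"]

    def test_early_parents_excluded_from_table(self, wt_tree):
        tab = ads_table(wt_tree)
        for parent in ("AB", "P1", "ABa", "ABp", "EMS", "P2"):
            if parent in tab.index:
                assert tab.loc[parent, "reason"] == "early-round-excluded"

    def test_abs_signed_conservation(self, wt_tree):
        tab = ads_table(wt_tree)
        unc = tab[~tab["censored"]]
        assert unc["signed_ads_min"].abs().sum() == pytest.approx(unc["ads_min"].sum())

    def test_frame_offset_invariance(self, make_toy):
        spans = {"ABa": (1, 9), "ABal": (10, 19), "ABar": (10, 24),
                 "ABala": (20, 30), "ABalp": (20, 30),
                 "ABara": (25, 30), "ABarp": (25, 30)}
        shifted = {c: (b + 7, l + 7) for c, (b, l) in spans.items()}
        a = compute_ads(build_lineage(chain_recording(make_toy, spans)), "ABa")
        b = compute_ads(build_lineage(chain_recording(make_toy, shifted)), "ABa")
        assert a["ads_min"] == b["ads_min"]


class TestCorrelationMatrix:
    def test_self_and_affine_invariance(self, wt_cycle_tables):
        t = wt_cycle_tables[0]
        scaled = t.copy()
        scaled["cycle_length_min"] = scaled["cycle_length_min"] * 1.1
        m = correlation_matrix([t, scaled])
        assert m.iloc[0, 0] == 1.0
        assert m.iloc[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_pearson(self, wt_cycle_tables):
        a, b = wt_cycle_tables[0], wt_cycle_tables[1]
        m = correlation_matrix([a, b])
        sa = a.loc[~a["censored"], "cycle_length_min"]
        sb = b.loc[~b["censored"], "cycle_length_min"]
        joined = pd.concat([sa, sb], axis=1, join="inner").to_numpy()
        x, y = joined[:, 0], joined[:, 1]
        r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert m.iloc[0, 1] == pytest.approx(r, abs=1e-12)

    def test_too_few_shared_cells_is_missing(self, make_toy):
        r1 = chain_recording(
            make_toy, {"ABa": (1, 9), "ABal": (10, 19), "ABar": (10, 19),
                       "ABala": (20, 25), "ABalp": (20, 25),
                       "ABara": (20, 25), "ABarp": (20, 25)})
        t1 = cycle_lengths(build_lineage(r1))
        m = correlation_matrix([t1, t1])
        # only two uncensored cells shared -> below the 3-cell floor
        assert np.isnan(m.iloc[0, 1])

    def test_global_slowdown_leaves_r_unchanged(self, wt_cycle_tables):
        slow = [
            t.assign(cycle_length_min=t["cycle_length_min"] * 1.3)
            for t in wt_cycle_tables[:4]
        ]
        m1 = correlation_matrix(wt_cycle_tables[:4]).to_numpy()
        m2 = correlation_matrix(slow).to_numpy()
        np.testing.assert_allclose(m1, m2, atol=1e-12)


class TestClustering:
    def test_identical_rows_merge_first_at_zero(self):
        m = pd.DataFrame([[0.0, 1.0], [0.0, 1.0], [4.0, 9.0]])
        out = cluster_embryos(m)
        z = out["linkage"]
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}
        assert z[0, 2] == 0.0

    def test_three_row_enumeration_oracle(self):
        # pairwise L1 distances d01=1, d02=5, d12=5: of the three possible
        # first merges, complete linkage must pick (0,1) and end at height 5
        m = pd.DataFrame([[0.0, 0.0], [0.5, 0.5], [5.0, 0.0]])
        z = cluster_embryos(m)["linkage"]
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}
        assert z[0, 2] == pytest.approx(1.0)
        assert z[1, 2] == pytest.approx(5.0)

    def test_leaf_order_is_permutation(self, wt_cycle_tables):
        m = correlation_matrix(wt_cycle_tables)
        out = cluster_embryos(m)
        assert sorted(out["leaf_order"]) == list(range(len(wt_cycle_tables)))


class TestGenerationSDProfile:
    def test_zero_noise_gives_zero_sd(self, wt_cycle_tables):
        t = wt_cycle_tables[0]
        profile = generation_sd_profile([t, t, t])
        assert (profile["mean_sd_min"] == 0).all()

    def test_increasing_with_generation(self, template):
        cohort = simulate_cohort(
            template, NoiseModel(sigma0=0.3, kappa=0.4), n=20, seed=21
        )
        tables = [cycle_lengths(build_lineage(r)) for r in cohort]
        profile = generation_sd_profile(tables)
        mid = profile[(profile["generation"] >= 3) & (profile["generation"] <= 8)]
        sds = mid["mean_sd_min"].to_numpy()
        assert len(sds) >= 4
        assert np.all(np.diff(sds) > 0)

    def test_min_n_filter(self, wt_cycle_tables):
        profile = generation_sd_profile(wt_cycle_tables, min_n=3)
        loose = generation_sd_profile(wt_cycle_tables, min_n=12)
        assert loose["n_cells"].sum() <= profile["n_cells"].sum()


def test_analysis_cutoff_is_350_cell_frame(wt_tree):
    from lineatime.model import cell_count_at

    cutoff = analysis_cutoff_frame(wt_tree)
    assert cutoff <= wt_tree.last_curated_frame
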
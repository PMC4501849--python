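import numpy as np
import pytest
from scipy import stats
from scipy.special import inv_boxcox
from scipy.spatial.transform import Rotation

from lineatime.model import build_lineage
from lineatime.simulate import PerturbationSpec, make_template, simulate_cohort, simulate_embryo
from lineatime.spatial import (
    angle_deviation,
    boxcox_lambda_mle,
    compute_transform,
    division_angles,
    last_four_cell_frame,
    normalize_axes,
    position_deviation,
    trajectory,
)


def rigid_motion(rec, seed):
    rng = np.random.default_rng(seed)
    q = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-50, 50, size=3)
    obs = rec.observations.copy()
    obs[["x", "y", "z"]] = obs[["x", "y", "z"]].to_numpy() @ q.T + t
    return rec.with_observations(obs)


class TestFourCellFrame:
    def test_before_any_second_round_division(self, wt_embryo, wt_tree):
        f = last_four_cell_frame(wt_embryo)
        assert f < wt_tree["ABa"].last_frame + 1
        assert f >= wt_tree["ABa"].birth_frame

    def test_missing_four_cell_stage_is_error(self, make_toy):
        rec = make_toy([(c, 1, i, 0, 0) for i, c in enumerate(
            ["ABal", "ABar", "ABpl", "ABpr", "MS", "E"])])
        with pytest.raises(ValueError, match="four-cell"):
            last_four_cell_frame(rec)


class TestNormalizeAxes:
    def test_canonical_four_cells_identity_rotation(self, make_toy):
        rec = make_toy([
            ("ABa", 1, -1.0, 0.0, 0.0),
            ("P2", 1, 1.0, 0.0, 0.0),
            ("ABp", 1, 0.0, -1.0, 0.0),
            ("EMS", 1, 0.0, 1.0, 0.0),
        ])
        norm, tf = normalize_axes(rec)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-12)
        xyz = norm.observations[["x", "y", "z"]].to_numpy()
        assert xyz[:, 0].min() == -1.0 and xyz[:, 0].max() == 1.0

    def test_rigid_motion_invariance(self, wt_embryo):
        base = normalize_axes(wt_embryo)[0].observations[["x", "y", "z"]].to_numpy()
        for seed in range(3):
            moved = rigid_motion(wt_embryo, seed)
            out = normalize_axes(moved)[0].observations[["x", "y", "z"]].to_numpy()
            assert np.abs(out - base).max() < 1e-9

    def test_all_coordinates_in_unit_cube(self, wt_embryo):
        xyz = normalize_axes(wt_embryo)[0].observations[["x", "y", "z"]].to_numpy()
        assert xyz.min() >= -1.0 - 1e-12 and xyz.max() <= 1.0 + 1e-12

    def test_reference_frame_rebased_to_zero(self, wt_embryo):
        norm, tf = normalize_axes(wt_embryo)
        assert tf.reference_frame == last_four_cell_frame(wt_embryo)
        four = norm.observations[norm.observations["frame"] == 0]
        assert set(four["cell"]) == {"ABa", "ABp", "EMS", "P2"}

    def test_rotation_right_handed(self, wt_embryo):
        tf = compute_transform(wt_embryo)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_geometry_rejected(self, make_toy):
        rec = make_toy([
            ("ABa", 1, -1.0, 0.0, 0.0), ("P2", 1, 1.0, 0.0, 0.0),
            ("ABp", 1, -0.5, 0.0, 0.0), ("EMS", 1, 0.5, 0.0, 0.0),
        ])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            normalize_axes(rec)


def angle_fixture(make_toy, v):
    """Toy already-rotated recording where ABa's daughters separate along v."""
    rows = [("ABa", 1, 0, 0, 0), ("ABa", 2, 0, 0, 0),
            ("ABal", 3, 0, 0, 0), ("ABal", 4, 0, 0, 0),
            ("ABar", 3, v[0], v[1], v[2]), ("ABar", 4, v[0], v[1], v[2])]
    rec = make_toy(rows)
    return rec, build_lineage(rec)


class TestDivisionAngles:
    def test_vector_along_ap(self, make_toy):
        rec, tree = angle_fixture(make_toy, (1.0, 0.0, 0.0))
        ang = division_angles(rec, tree, "ABa")
        assert ang["AP-LR"] == pytest.approx(0.0, abs=1e-9)
        assert ang["AP-DV"] == pytest.approx(0.0, abs=1e-9)
        assert ang["LR-DV"] == pytest.approx(90.0, abs=1e-9)

    def test_diagonal_vector(self, make_toy):
        s = 1 / np.sqrt(2)
        rec, tree = angle_fixture(make_toy, (s, s, 0.0))
        ang = division_angles(rec, tree, "ABa")
        assert ang["AP-LR"] == pytest.approx(0.0, abs=1e-9)
        assert ang["AP-DV"] == pytest.approx(45.0, abs=1e-9)
        assert ang["LR-DV"] == pytest.approx(45.0, abs=1e-9)

    def test_scale_invariance_and_direction_cosines(self, make_toy):
        v = np.array([0.3, -0.5, 0.8])
        a1 = division_angles(*angle_fixture(make_toy, v), "ABa")
        a2 = division_angles(*angle_fixture(make_toy, 7.0 * v), "ABa")
        for plane in a1:
            assert a1[plane] == pytest.approx(a2[plane], abs=1e-9)
        cos2 = sum(np.sin(np.radians(a)) ** 2 for a in a1.values())
        assert cos2 == pytest.approx(1.0, abs=1e-9)

    def test_zero_vector_is_error(self, make_toy):
        rec, tree = angle_fixture(make_toy, (0.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="zero-length"):
            division_angles(rec, tree, "ABa")


class TestTrajectory:
    def test_chain_and_endpoints(self, wt_embryo):
        path = trajectory(wt_embryo, "ABalaa", start="ABa")
        assert path["cell"].iloc[0] == "ABa"
        assert path["cell"].iloc[-1] == "ABalaa"
        assert path["frame"].is_monotonic_increasing

    def test_length_is_sum_of_segments(self, wt_embryo, wt_tree):
        path = trajectory(wt_embryo, "ABala", start="ABa")
        expected = sum(
            wt_tree[c].last_frame - wt_tree[c].birth_frame + 1
            for c in ("ABa", "ABal", "ABala")
        )
        assert len(path) == expected

    def test_non_ancestor_start_is_error(self, wt_embryo):
        with pytest.raises(ValueError, match="not an observed ancestor"):
            trajectory(wt_embryo, "ABala", start="P1")


@pytest.fixture(scope="module")
def norm_cohort(template):
    cohort = simulate_cohort(template, n=12, seed=55)
    return [normalize_axes(r)[0] for r in cohort]


class TestPositionDeviation:
    def test_centroid_gives_high_p(self, norm_cohort):
        out = position_deviation(norm_cohort[0], norm_cohort[1:], "ABala")
        assert out["p"] > 0.01

    def test_large_shift_detected(self, template, norm_cohort):
        # shift a subtree below the four-cell stage so the axis definition
        # itself stays put
        shifted = simulate_embryo(
            template, seed=501,
            perturbation=PerturbationSpec(position_shift={"ABal": (0.5, 0.3, 0.2)}),
        )
        out = position_deviation(normalize_axes(shifted)[0], norm_cohort, "ABala")
        assert out["p"] < 0.05

    def test_absent_cell_is_error(self, norm_cohort):
        with pytest.raises(KeyError):
            position_deviation(norm_cohort[0], norm_cohort[1:], "ABalappppaaa")


class TestBoxCox:
    def test_lognormal_lambda_near_zero(self):
        x = np.exp(np.random.default_rng(2).normal(0, 0.5, size=91))
        assert abs(boxcox_lambda_mle(x)) < 0.3

    def test_shifted_normal_lambda_near_one(self):
        x = np.random.default_rng(3).normal(50, 5, size=91)
        assert boxcox_lambda_mle(x) == pytest.approx(1.0, abs=0.6)

    def test_matches_scipy_profile_mle(self):
        x = np.random.default_rng(4).lognormal(1.0, 0.4, size=60)
        ours = boxcox_lambda_mle(x)
        theirs = stats.boxcox_normmax(x, method="mle")
        assert ours == pytest.approx(float(theirs), abs=1e-4)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            boxcox_lambda_mle([0.0] + [1.0] * 20)


class TestAngleDeviation:
    def test_wildtype_mean_gives_p_near_one(self):
        wt = np.random.default_rng(6).normal(45, 5, size=91)
        lam = boxcox_lambda_mle(np.maximum(wt, 0.1))
        t = stats.boxcox(np.maximum(wt, 0.1), lmbda=lam)
        back = float(inv_boxcox(t.mean(), lam))
        out = angle_deviation(wt, back)
        assert out["p"] > 0.9

    def test_z_quantile_gives_nominal_p(self):
        wt = np.random.default_rng(7).normal(45, 5, size=91)
        lam = boxcox_lambda_mle(np.maximum(wt, 0.1))
        t = stats.boxcox(np.maximum(wt, 0.1), lmbda=lam)
        keep = np.abs(t - t.mean()) < 3 * t.std(ddof=1)
        mu, sd = t[keep].mean(), t[keep].std(ddof=1)
        probe = float(inv_boxcox(mu + 2.575829 * sd, lam))
        out = angle_deviation(wt, probe)
        assert out["p"] == pytest.approx(0.01, abs=1e-4)

    def test_outlier_removed_after_lambda_fit(self):
        rng = np.random.default_rng(8)
        wt = rng.normal(45, 5, size=90)
        lam_clean_sample = boxcox_lambda_mle(wt)
        spiked = np.append(wt, 45 + 40.0)  # far beyond 3 SD
        out = angle_deviation(spiked, 45.0)
        ref = out["reference"]
        assert ref.n_outliers_removed == 1
        assert ref.n == 90
        # lambda was fitted on the spiked sample, before de-noising
        assert ref.lam == pytest.approx(boxcox_lambda_mle(spiked), abs=1e-9)
        assert ref.lam != pytest.approx(lam_clean_sample, abs=1e-12)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            angle_deviation([40.0] * 5, 45.0)
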
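"""Embryo coordinate normalization and spatial statistics.

Embryos are registered on the body axes defined at the last four-cell
frame: the ABa -> P2 direction is anterior-posterior (A-P) and the
ABp -> EMS direction (orthogonalized against A-P) is labelled left-right
(L-R), with dorsal-ventral (D-V) completing a right-handed frame. After
rotation each axis is affinely mapped so the embryo spans [-1, 1], which
makes positions comparable across embryos of different sizes. Division
angles are measured in the rotated but *unscaled* frame, because the
anisotropic scaling would distort angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import nomenclature as nom
from .model import EmbryoRecording, LineageTree
from .reference import dagostino_k2, tail_probability

__all__ = [
    "AngleReference",
    "EmbryoFrameTransform",
    "angle_deviation",
    "boxcox_lambda_mle",
    "division_angles",
    "last_four_cell_frame",
    "normalize_axes",
    "position_deviation",
    "trajectory",
]

FOUR_CELLS = frozenset({"ABa", "ABp", "EMS", "P2"})
PLANES = ("AP-LR", "AP-DV", "LR-DV")
#: index of the axis normal to each reference plane (rows of the rotation)
PLANE_NORMAL_AXIS = {"AP-LR": 2, "AP-DV": 1, "LR-DV": 0}


@dataclass
class EmbryoFrameTransform:
    """Rigid rotation + per-axis [-1, 1] scaling of one embryo."""

    reference_frame: int
    origin: np.ndarray  # (3,) um, centroid of the four cells
    rotation: np.ndarray  # (3, 3), rows = A-P, L-R, D-V unit vectors
    axis_min: np.ndarray  # (3,) rotated-coordinate extremes
    axis_max: np.ndarray

    def rotate(self, xyz: np.ndarray) -> np.ndarray:
        """Map raw micrometre coordinates into embryo axes (unscaled)."""
        return (np.asarray(xyz, dtype=float) - self.origin) @ self.rotation.T

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        """Map raw coordinates into normalized [-1, 1] embryo coordinates."""
        rot = self.rotate(xyz)
        span = self.axis_max - self.axis_min
        safe = np.where(span > 0, span, 1.0)
        out = 2.0 * (rot - self.axis_min) / safe - 1.0
        return np.where(span > 0, out, 0.0)


def last_four_cell_frame(recording: EmbryoRecording) -> int:
    """The greatest frame at which exactly {ABa, ABp, EMS, P2} are present."""
    obs = recording.observations
    per_frame = obs.groupby("frame")["cell"].agg(frozenset)
    hits = per_frame.index[per_frame == FOUR_CELLS]
    if not len(hits):
        raise ValueError(
            f"{recording.id}: no four-cell (ABa/ABp/EMS/P2) frame — "
            "recording may start too late"
        )
    return int(hits.max())


def _four_cell_positions(recording: EmbryoRecording, frame: int) -> dict[str, np.ndarray]:
    obs = recording.observations
    sel = obs[obs["frame"] == frame].set_index("cell")
    return {c: sel.loc[c, ["x", "y", "z"]].to_numpy(dtype=float) for c in FOUR_CELLS}


def compute_transform(recording: EmbryoRecording) -> EmbryoFrameTransform:
    """Derive the embryo-frame transform from the last four-cell frame."""
    ref_frame = last_four_cell_frame(recording)
    pos = _four_cell_positions(recording, ref_frame)
    ap = pos["P2"] - pos["ABa"]
    n_ap = np.linalg.norm(ap)
    lr_raw = pos["EMS"] - pos["ABp"]
    if n_ap == 0:
        raise ValueError(f"{recording.id}: ABa and P2 coincide")
    ap = ap / n_ap
    lr = lr_raw - (lr_raw @ ap) * ap  # Gram-Schmidt against A-P
    n_lr = np.linalg.norm(lr)
    if n_lr < 1e-9 * max(1.0, np.linalg.norm(lr_raw)):
        raise ValueError(f"{recording.id}: degenerate four-cell geometry (collinear)")
    lr = lr / n_lr
    dv = np.cross(ap, lr)  # right-handed by construction
    rotation = np.vstack([ap, lr, dv])
    origin = np.mean(list(pos.values()), axis=0)

    rotated = (recording.observations[["x", "y", "z"]].to_numpy(dtype=float) - origin) @ rotation.T
    return EmbryoFrameTransform(
        reference_frame=ref_frame,
        origin=origin,
        rotation=rotation,
        axis_min=rotated.min(axis=0),
        axis_max=rotated.max(axis=0),
    )


def normalize_axes(
    recording: EmbryoRecording,
) -> tuple[EmbryoRecording, EmbryoFrameTransform]:
    """Register a recording on its body axes and normalize to [-1, 1].

    Returns a new recording whose positions are normalized coordinates and
    whose frame index is re-based so the reference (last four-cell) frame is
    0, plus the transform (whose ``rotate`` method gives the unscaled frame
    used for angle statistics).
    """
    tf = compute_transform(recording)
    obs = recording.observations.copy()
    xyz = tf.apply(obs[["x", "y", "z"]].to_numpy(dtype=float))
    obs[["x", "y", "z"]] = xyz
    obs["frame"] = obs["frame"].astype(int) - tf.reference_frame
    out = recording.with_observations(
        obs,
        normalized=True,
        last_curated_frame=recording.last_curated_frame - tf.reference_frame,
    )
    return out, tf


def trajectory(
    recording: EmbryoRecording,
    target: str,
    start: str | None = None,
) -> pd.DataFrame:
    """Lineal migration path: per-frame positions of the ancestor chain from
    *start* (default: the observed root of the target's lineage) down to the
    target's last frame."""
    obs = recording.observations
    present = set(obs["cell"].unique())
    if target not in present:
        raise KeyError(f"{target} not observed in {recording.id}")
    chain = [target]
    while chain[-1] != "P0":
        mother = nom.mother_of(chain[-1])
        if mother not in present:
            break
        chain.append(mother)
    chain.reverse()
    if start is not None:
        if start not in chain:
            raise ValueError(f"{start} is not an observed ancestor of {target}")
        chain = chain[chain.index(start):]
    parts = []
    for cell in chain:
        seg = obs[obs["cell"] == cell].sort_values("frame")
        parts.append(seg[["cell", "frame", "x", "y", "z"]])
    path = pd.concat(parts, ignore_index=True)
    path.insert(2, "time_min", path["frame"] * recording.frame_interval_min)
    return path


def position_deviation(
    perturbed: EmbryoRecording,
    wildtype_cohort: list[EmbryoRecording],
    cell: str,
    min_n: int = 8,
) -> dict:
    """Deviation of a cell's final position from the wild-type centroid.

    All recordings must be normalized. The wild-type centroid and the
    distribution of wild-type distances to it define a normal model; the
    perturbed embryo's distance is assigned its upper-tail probability.
    Per-coordinate K-squared normality of the wild-type spread is reported.
    """
    def final_position(rec: EmbryoRecording) -> np.ndarray:
        if not rec.normalized:
            raise ValueError(f"{rec.id}: recording is not axis-normalized")
        sel = rec.positions_of(cell)
        return sel.iloc[-1][["x", "y", "z"]].to_numpy(dtype=float)

    wt_pos = np.array([final_position(r) for r in wildtype_cohort])
    if len(wt_pos) < min_n:
        raise ValueError(f"cell {cell} present in only {len(wt_pos)} wild-type embryos")
    centroid = wt_pos.mean(axis=0)
    wt_dist = np.linalg.norm(wt_pos - centroid, axis=1)
    d = float(np.linalg.norm(final_position(perturbed) - centroid))
    mean_d, sd_d = float(wt_dist.mean()), float(wt_dist.std(ddof=1))
    coord_k2 = {
        ax: dagostino_k2(wt_pos[:, i])[1] if len(wt_pos) >= 8 else np.nan
        for i, ax in enumerate(("ap", "lr", "dv"))
    }
    p = tail_probability(mean_d, sd_d, d, side="upper")
    return {
        "distance": d,
        "p": p,
        "centroid": centroid,
        "wt_mean_distance": mean_d,
        "wt_sd_distance": sd_d,
        "coordinate_normality_p": coord_k2,
        "n_wildtype": len(wt_pos),
    }


def division_angles(
    recording: EmbryoRecording,
    tree: LineageTree,
    cell: str,
    transform: EmbryoFrameTransform | None = None,
) -> dict[str, float]:
    """Angles of a division axis against the three reference planes.

    The division vector joins the two newborn daughter nuclei at their birth
    frame; the angle to a plane with unit normal n is
    arcsin(|v . n| / ||v||), reported in degrees in [0, 90]. Computed in the
    rotated, unscaled embryo frame: pass the raw recording with its
    transform, or an already-rotated recording with ``transform=None``.
    """
    node = tree[cell]
    if node.daughters is None:
        raise ValueError(f"{cell} did not divide")
    d1, d2 = node.daughters
    birth = node.last_frame + 1
    obs = recording.observations
    pts = {}
    for d in (d1, d2):
        sel = obs[(obs["cell"] == d) & (obs["frame"] == birth)]
        if not len(sel):
            raise ValueError(f"{d} not observed at its birth frame {birth}")
        pts[d] = sel.iloc[0][["x", "y", "z"]].to_numpy(dtype=float)
    v = pts[d2] - pts[d1]
    if transform is not None:
        v = v @ transform.rotation.T
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError(f"{cell}: zero-length division vector")
    angles = {}
    for plane in PLANES:
        sin_theta = abs(v[PLANE_NORMAL_AXIS[plane]]) / norm
        angles[plane] = float(np.degrees(np.arcsin(min(1.0, sin_theta))))
    return angles


def boxcox_lambda_mle(sample, bounds: tuple[float, float] = (-5.0, 5.0)) -> float:
    """Box-Cox power parameter by profile maximum likelihood.

    Maximizes the standard Box-Cox profile log-likelihood over the bounded
    interval with a scalar optimizer (tolerance 1e-6). All values must be
    strictly positive and n >= 10.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 10:
        raise ValueError(f"need n >= 10 positive values, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, x),
        bounds=bounds,
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


@dataclass
class AngleReference:
    """Wild-type division-angle model for one (cell, plane)."""

    cell: str
    plane: str
    lam: float
    mean_t: float  # mean of transformed, de-noised sample
    sd_t: float
    n: int
    n_outliers_removed: int
    k2_p: float


def angle_deviation(
    wildtype_angles,
    perturbed_angle: float,
    cell: str = "",
    plane: str = "",
    angle_floor_deg: float = 0.1,
    outlier_sd: float = 3.0,
) -> dict:
    """Significance of a perturbed division angle against the wild type.

    The wild-type sample is Box-Cox transformed (lambda fitted first by
    MLE), then de-noised in a single pass by removing points at least 3 SD
    from the transformed mean; the perturbed angle is transformed with the
    same lambda and assigned a two-sided normal tail probability. Angles are
    clamped to a small positive floor before transforming.
    """
    wt = np.maximum(np.asarray(wildtype_angles, dtype=float), angle_floor_deg)
    if wt.size < 10:
        raise ValueError("need at least 10 wild-type angles")
    lam = boxcox_lambda_mle(wt)
    t = stats.boxcox(wt, lmbda=lam)
    mu, sd = t.mean(), t.std(ddof=1)
    keep = np.abs(t - mu) < outlier_sd * sd if sd > 0 else np.ones_like(t, bool)
    t_clean = t[keep]
    if t_clean.size < 8:
        raise ValueError("fewer than 8 wild-type angles after outlier removal")
    mu, sd = float(t_clean.mean()), float(t_clean.std(ddof=1))
    k2_p = dagostino_k2(t_clean)[1] if np.ptp(t_clean) > 0 else np.nan
    x = stats.boxcox(
        np.array([max(float(perturbed_angle), angle_floor_deg)]), lmbda=lam
    )[0]
    z = (x - mu) / sd if sd > 0 else np.inf * np.sign(x - mu)
    p = tail_probability(mu, sd, float(x), side="two")
    return {
        "z": float(z),
        "p": p,
        "reference": AngleReference(
            cell=cell,
            plane=plane,
            lam=lam,
            mean_t=mu,
            sd_t=sd,
            n=int(t_clean.size),
            n_outliers_removed=int((~keep).sum()),
            k2_p=float(k2_p),
        ),
    }
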
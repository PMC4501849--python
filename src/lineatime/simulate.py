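"""Seeded generator of synthetic wild-type and perturbed embryo recordings.

The generator emulates the statistical structure of curated lineaging
output that the analysis assumes, without modelling morphogenesis:

* an invariant binary lineage with Sulston names and per-cell mean cycle
  lengths that grow with generation;
* designated asynchronous sister pairs realized as mean cycle-length
  differences between the daughters (the P4/D germline-muscle pair carries
  the largest offset);
* per-cell cycle-length noise whose SD grows with generation, plus a shared
  per-embryo pace factor that correlates whole embryos;
* 1.5-minute frame quantization of division times (round half up), which
  reproduces the +/- one-frame noise floor of real curated data;
* curation cutoff at ~350 cells or frame 240;
* nucleus positions placed recursively inside a 2:1:1 ellipsoid, with the
  canonical diamond arrangement at the four-cell stage;
* a tissue-marker intensity restricted to one sublineage;
* perturbation phenotypes: ADS collapse, slowdown, variance inflation,
  arrest, position/angle shifts, marker knockout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nomenclature as nom
from .model import EmbryoRecording

__all__ = [
    "LineageTemplate",
    "NoiseModel",
    "PerturbationSpec",
    "default_async_pairs",
    "make_template",
    "simulate_cohort",
    "simulate_embryo",
    "simulate_screen_dataset",
]

FRAME_INTERVAL_MIN = 1.5
#: ellipsoid semi-axes in micrometres (2:1:1, ~50 x 25 x 25 um embryo)
ELLIPSOID = np.array([24.0, 12.0, 12.0])

#: mean cycle lengths (minutes) of the early cells, chosen to give a
#: two-cell start and a four-cell stage lasting ~10 frames
SPECIAL_MEANS = {
    "AB": 16.0, "P1": 18.0,
    "ABa": 17.0, "ABp": 17.5, "EMS": 16.5, "P2": 17.5,
}

#: canonical placements (um) for the early cells
SPECIAL_POSITIONS = {
    "AB": (-10.0, 0.0, 0.0), "P1": (10.0, 0.0, 0.0),
    "ABa": (-14.0, 0.0, 2.0), "ABp": (-3.0, 0.0, 9.0),
    "EMS": (3.0, 0.0, -9.0), "P2": (14.0, 0.0, -2.0),
}
#: offset directions for special daughters of later founder divisions
SPECIAL_DIRECTIONS = {
    "MS": (-0.5, 0.3, -0.8), "E": (0.3, -0.3, -0.9),
    "C": (0.2, 0.4, 0.9), "P3": (0.9, -0.2, -0.3),
    "D": (-0.3, 0.5, -0.5), "P4": (0.8, -0.4, 0.2),
    "Z2": (0.5, 0.5, 0.0), "Z3": (0.5, -0.5, 0.0),
}

_CATEGORY_CYCLE = ("different-fate", "same-fate", "blast-vs-terminal")


def default_async_pairs() -> dict[str, tuple[float, str]]:
    """The 12 designated asynchronous pairs: parent -> (offset min, category).

    Offsets span 8-40 minutes; the P4/D sisters (parent P3) carry the
    largest, mirroring the germline's delayed division.
    """
    return {
        "P3": (40.0, "different-fate"),
        "ABala": (20.0, "different-fate"),
        "ABplp": (18.0, "different-fate"),
        "ABpl": (16.0, "different-fate"),
        "MSa": (13.0, "same-fate"),
        "ABpr": (12.0, "same-fate"),
        "C": (11.0, "same-fate"),
        "ABar": (10.0, "blast-vs-terminal"),
        "E": (9.0, "same-fate"),
        "Ca": (8.5, "same-fate"),
        "ABal": (8.0, "different-fate"),
        "MS": (14.0, "different-fate"),
    }


@dataclass(frozen=True)
class NoiseModel:
    """Cycle-length noise: per-cell SD sigma(c) = sigma0 + kappa * generation,
    a shared per-embryo relative pace factor with SD ``rho``, and a global
    speed multiplier."""

    sigma0: float = 0.3
    kappa: float = 0.12
    rho: float = 0.02
    speed: float = 1.0

    def __post_init__(self):
        if self.sigma0 <= 0 or self.kappa < 0:
            raise ValueError("sigma0 must be > 0 and kappa >= 0")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")

    def sigma(self, generation: int) -> float:
        return self.sigma0 + self.kappa * generation


@dataclass(frozen=True)
class PerturbationSpec:
    """Phenotype to inject into a simulated embryo; all fields optional."""

    ads_factor: dict[str, float] = field(default_factory=dict)  # parent -> factor
    slowdown: float = 1.0
    variance_inflation: dict[str, float] = field(default_factory=dict)  # founder -> x
    arrest_frame: int | None = None
    arrest_cell_count: int | None = None
    position_shift: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    angle_rotation: tuple[str, float, str] | None = None  # (cell, degrees, plane)
    expression_knockout: str | None = None  # sublineage root

    def __post_init__(self):
        if self.slowdown < 0 or any(v < 0 for v in self.ads_factor.values()):
            raise ValueError("factors must be >= 0")


@dataclass(frozen=True)
class LineageTemplate:
    """Invariant lineage with per-cell mean cycle lengths and metadata."""

    rounds: int
    seed: int
    mean_cycle_min: dict[str, float]  # per dividing cell
    division_axis: dict[str, str]  # parent -> axis letter pair
    async_pairs: dict[str, tuple[float, str]]  # parent -> (offset, category)
    marker_root: str = "E"
    marker_level: float = 1000.0

    def cells(self) -> list[str]:
        """All cells of the template (dividing cells plus terminal leaves)."""
        names = set(self.mean_cycle_min)
        for parent, axis in self.division_axis.items():
            names.update(nom.daughters_of(parent, axis))
        return sorted(names, key=nom.sort_key)

    def daughters(self, name: str) -> tuple[str, str] | None:
        if name not in self.division_axis:
            return None
        return nom.daughters_of(name, self.division_axis[name])


#: lineage-specific pace multipliers: intestine (E) and the posterior muscle
#: lineages divide slower than AB, as in the real embryo, which gives the
#: cycle-length vector the large across-cell spread real recordings show
FOUNDER_PACE = {
    "ABa": 0.92, "ABp": 0.92, "MS": 1.0, "E": 1.45,
    "C": 1.2, "D": 1.35, "P4": 1.1,
}


def make_template(
    rounds: int = 9,
    seed: int = 0,
    async_pair_spec: dict[str, tuple[float, str]] | None = None,
    base_min: float = 10.0,
    growth_min_per_gen: float = 3.2,
    jitter_frac: float = 0.10,
    founder_pace: dict[str, float] | None = None,
) -> LineageTemplate:
    """Build the invariant lineage template.

    Baseline mean cycle length grows linearly with generation
    (``base_min + growth_min_per_gen * g``), scaled by a founder-lineage
    pace factor, with a deterministic per-pair jitter; designated pairs add
    their offset to the second daughter's mean. Deterministic for fixed
    inputs.
    """
    if rounds < 5:
        raise ValueError("need rounds >= 5 so the 350-cell stage is reachable")
    async_pairs = (
        dict(async_pair_spec) if async_pair_spec is not None else default_async_pairs()
    )
    pace = founder_pace if founder_pace is not None else FOUNDER_PACE
    rng = np.random.default_rng(seed)

    division_axis: dict[str, str] = {}
    means: dict[str, float] = dict(SPECIAL_MEANS)

    def base_mean(name: str) -> float:
        g = nom.generation_of(name)
        factor = pace.get(nom.founder_of(name), 1.0)
        jitter = 1.0 + jitter_frac * float(rng.standard_normal())
        return (base_min + growth_min_per_gen * g) * factor * jitter

    # sisters share one jittered baseline: without a designated offset their
    # mean asynchrony is zero, so only noise separates them

    # breadth-first over the canonical skeleton plus generic subdivisions
    frontier = ["P0"]
    while frontier:
        name = frontier.pop(0)
        g = nom.generation_of(name)
        if g >= rounds or name in ("Z2", "Z3"):
            continue
        if name in nom.SPECIAL_DAUGHTERS:
            axis = "ap"  # unused for table names
        elif name in ("ABa", "ABp"):
            axis = "lr"
        else:
            axis = "ap"
        division_axis[name] = axis
        ds = nom.daughters_of(name, axis)
        shared = base_mean(ds[0])
        for d in ds:
            if d not in means:
                means[d] = shared
            frontier.append(d)

    # realize designated offsets on the daughters' means
    for parent, (offset, _cat) in async_pairs.items():
        if parent not in division_axis:
            raise ValueError(f"designated pair parent {parent} not in template")
        d1, d2 = nom.daughters_of(parent, division_axis[parent])
        if means.get(d1, 1.0) <= 0 or means.get(d1, 1.0) + offset <= 0:
            raise ValueError(f"offset for {parent} drives a mean cycle <= 0")
        if d2 in means:
            means[d2] = means[d1] + offset

    # terminal leaves (generation == rounds, or Z2/Z3) have no mean: they
    # never divide in the template
    means = {k: v for k, v in means.items() if k in division_axis}
    return LineageTemplate(
        rounds=rounds,
        seed=seed,
        mean_cycle_min=means,
        division_axis=division_axis,
        async_pairs=async_pairs,
    )


def _direction(name: str, rng: np.random.Generator) -> np.ndarray:
    """Unit placement direction for a division, from the daughter suffix."""
    if name in SPECIAL_DIRECTIONS:
        v = np.asarray(SPECIAL_DIRECTIONS[name], dtype=float)
        return v / np.linalg.norm(v)
    letter = name[-1]
    base = {
        "a": (-1, 0, 0), "p": (1, 0, 0),
        "l": (0, -1, 0), "r": (0, 1, 0),
        "d": (0, 0, 1), "v": (0, 0, -1),
    }[letter]
    v = np.asarray(base, dtype=float) + 0.35 * rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _clamp_to_ellipsoid(p: np.ndarray, fill: float = 0.92) -> np.ndarray:
    q = float(np.sum((p / ELLIPSOID) ** 2))
    if q > fill:
        p = p * math.sqrt(fill / q)
    return p


def _rotation_about(axis_index: int, degrees: float) -> np.ndarray:
    c, s = math.cos(math.radians(degrees)), math.sin(math.radians(degrees))
    i, j = [k for k in range(3) if k != axis_index]
    rot = np.eye(3)
    rot[i, i] = c
    rot[j, j] = c
    rot[i, j] = -s
    rot[j, i] = s
    return rot


_PLANE_ROT_AXIS = {"AP-LR": 2, "AP-DV": 1, "LR-DV": 0}


def simulate_embryo(
    template: LineageTemplate,
    noise: NoiseModel | None = None,
    perturbation: PerturbationSpec | None = None,
    seed: int = 0,
    recording_id: str = "sim",
    target_gene: str = "wild-type",
    replicate: int = 1,
    cell_target: int = 350,
    overshoot_frames: int = 5,
    max_frame: int = 240,
    frame_jitter_um: float = 0.15,
    rigid_placement: bool = True,
) -> EmbryoRecording:
    """Simulate one embryo recording from the template.

    Each cell's cycle is ``slowdown * mu(c) * (1 + u) + eps`` with a shared
    per-embryo factor u ~ N(0, rho^2) and eps ~ N(0, sigma(c)^2 *
    variance_inflation). Division times are quantized to 1.5-minute frames
    (round half up) and daughters appear one frame after the mother's last.
    The recording is truncated at the first of: *cell_target* cells reached
    plus a small overshoot, frame ``max_frame``, or an arrest condition.
    """
    noise = noise or NoiseModel()
    pert = perturbation or PerturbationSpec()
    rng = np.random.default_rng(seed)
    dt = FRAME_INTERVAL_MIN
    u = noise.rho * float(rng.standard_normal())

    # effective mean cycles with ADS factors applied: scale the pair's
    # daughter mean-difference about the pair midpoint
    means = dict(template.mean_cycle_min)
    for parent, factor in pert.ads_factor.items():
        d1, d2 = template.daughters(parent) or (None, None)
        if d1 is None or d1 not in means or d2 not in means:
            continue
        mid = 0.5 * (means[d1] + means[d2])
        half = 0.5 * (means[d2] - means[d1]) * factor
        means[d1], means[d2] = mid - half, mid + half

    def inflation(name: str) -> float:
        founder = nom.founder_of(name)
        for root, x in pert.variance_inflation.items():
            if nom.is_ancestor(root, name):
                return x
        return pert.variance_inflation.get(founder, 1.0)

    # --- division schedule ----------------------------------------------------
    birth_time: dict[str, float] = {"AB": 0.0, "P1": 0.0}
    birth_frame: dict[str, int] = {"AB": 1, "P1": 1}
    div_frame: dict[str, int | None] = {}
    order = sorted(template.cells(), key=nom.sort_key)
    for name in order:
        if name not in birth_frame:
            continue  # descendants of undivided cells are added as we go
        daughters = template.daughters(name)
        if daughters is None or name not in means:
            div_frame[name] = None
            continue
        sigma = noise.sigma(nom.generation_of(name)) * math.sqrt(inflation(name))
        # a global slowdown rescales the whole programme, noise included, so
        # relative timings (and hence Pearson r between embryos) survive it
        cycle = pert.slowdown * noise.speed * (
            means[name] * (1.0 + u) + sigma * float(rng.standard_normal())
        )
        cycle = max(cycle, dt)  # a cell lives at least one frame
        t_div = birth_time[name] + cycle
        f_div = max(int(math.floor(t_div / dt + 0.5)), birth_frame[name])
        div_frame[name] = f_div
        for d in daughters:
            birth_time[d] = t_div
            birth_frame[d] = f_div + 1

    # --- truncation -----------------------------------------------------------
    events: list[tuple[int, int]] = []
    for name, bf in birth_frame.items():
        events.append((bf, +1))
        df_ = div_frame.get(name)
        if df_ is not None:
            events.append((df_ + 1, -1))
    events.sort()
    count, reach_frame = 0, None
    for f, delta in events:
        count += delta
        if count >= cell_target and reach_frame is None:
            reach_frame = f
    cutoff = max_frame if reach_frame is None else min(reach_frame + overshoot_frames, max_frame)
    if pert.arrest_cell_count is not None:
        count, arrest_at = 0, None
        for f, delta in events:
            count += delta
            if count >= pert.arrest_cell_count and arrest_at is None:
                arrest_at = f
        if arrest_at is not None:
            cutoff = min(cutoff, arrest_at)
    if pert.arrest_frame is not None:
        cutoff = min(cutoff, pert.arrest_frame)
    four_cell_complete = max(birth_frame[c] for c in ("ABa", "ABp", "EMS", "P2"))
    if cutoff <= four_cell_complete:
        raise ValueError(
            "arrest before the four-cell stage: recordings must contain the "
            "reference frame"
        )

    # --- positions ------------------------------------------------------------
    base_pos: dict[str, np.ndarray] = {
        n: np.asarray(p, dtype=float) + 0.6 * rng.standard_normal(3)
        for n, p in SPECIAL_POSITIONS.items()
    }
    angle_cell = pert.angle_rotation[0] if pert.angle_rotation else None
    for name in order:
        if name not in birth_frame or name in base_pos:
            continue
        parent = nom.mother_of(name)
        if parent not in base_pos:
            continue
        g = nom.generation_of(name)
        r = 18.0 * 2.0 ** (-g / 3.0)
        # the daughter's suffix letter (or special-direction entry) already
        # encodes which side of the division it takes
        direction = _direction(name, rng)
        offset = 0.5 * r * direction + 0.5 * rng.standard_normal(3)
        if angle_cell is not None and parent == angle_cell:
            rot = _rotation_about(
                _PLANE_ROT_AXIS[pert.angle_rotation[2]], pert.angle_rotation[1]
            )
            offset = offset @ rot.T
        base_pos[name] = _clamp_to_ellipsoid(base_pos[parent] + offset)

    for root, shift in pert.position_shift.items():
        delta = np.asarray(shift, dtype=float) * ELLIPSOID
        for name in base_pos:
            if nom.is_ancestor(root, name):
                base_pos[name] = base_pos[name] + delta

    # arbitrary imaging orientation: rotation about z plus translation
    if rigid_placement:
        theta = float(rng.uniform(0, 2 * np.pi))
        rot_z = _rotation_about(2, math.degrees(theta))
        shift = np.array([40.0, 40.0, 18.0]) + 4.0 * rng.standard_normal(3)
    else:
        rot_z = np.eye(3)
        shift = np.zeros(3)

    # --- marker intensity -----------------------------------------------------
    marker_root = template.marker_root
    knockout = pert.expression_knockout

    def intensity_of(name: str, nframes: int) -> np.ndarray:
        background = np.abs(rng.normal(50.0, 15.0, size=nframes))
        in_marker = nom.is_ancestor(marker_root, name)
        if in_marker and not (knockout and nom.is_ancestor(knockout, name)):
            return background + template.marker_level
        return background

    # --- assemble observation table -------------------------------------------
    frames_col, cells_col, pos_rows, intens = [], [], [], []
    for name, bf in birth_frame.items():
        if bf > cutoff or name not in base_pos:
            continue
        lf = div_frame.get(name)
        lf = cutoff if lf is None else min(lf, cutoff)
        nframes = lf - bf + 1
        if nframes <= 0:
            continue
        frames = np.arange(bf, lf + 1)
        pos = base_pos[name] + frame_jitter_um * rng.standard_normal((nframes, 3))
        pos = pos @ rot_z.T + shift
        frames_col.append(frames)
        cells_col.extend([name] * nframes)
        pos_rows.append(pos)
        intens.append(intensity_of(name, nframes))

    obs = pd.DataFrame(
        {
            "cell": cells_col,
            "frame": np.concatenate(frames_col),
            "x": np.concatenate(pos_rows)[:, 0],
            "y": np.concatenate(pos_rows)[:, 1],
            "z": np.concatenate(pos_rows)[:, 2],
            "intensity": np.concatenate(intens),
        }
    )
    if not (obs.loc[obs["frame"] == 1, "cell"].nunique() >= 2):
        raise ValueError("arrest before the four-cell stage is not representable")
    rec = EmbryoRecording(
        id=recording_id,
        observations=obs.sort_values(["cell", "frame"], kind="stable").reset_index(drop=True),
        target_gene=target_gene,
        replicate=replicate,
        frame_interval_min=dt,
        last_curated_frame=int(cutoff),
        marker=f"{marker_root}-marker",
    )
    return rec


def _spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]


def simulate_cohort(
    template: LineageTemplate,
    noise: NoiseModel | None = None,
    n: int = 91,
    seed: int = 0,
    id_prefix: str = "wt",
    perturbation: PerturbationSpec | None = None,
    target_gene: str = "wild-type",
    **kwargs,
) -> list[EmbryoRecording]:
    """Simulate n independent embryos with seeds derived from a master seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    seeds = _spawn_seeds(seed, n)
    return [
        simulate_embryo(
            template,
            noise,
            perturbation,
            seed=s,
            recording_id=f"{id_prefix}{i:03d}",
            target_gene=target_gene,
            replicate=i + 1,
            **kwargs,
        )
        for i, s in enumerate(seeds)
    ]


def simulate_screen_dataset(
    template: LineageTemplate,
    noise: NoiseModel | None = None,
    gene_specs: dict[str, PerturbationSpec] | None = None,
    n_wildtype: int = 20,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[list[EmbryoRecording], dict[str, list[EmbryoRecording]], pd.DataFrame]:
    """Wild-type cohort plus per-gene replicate recordings and a truth table.

    Returns (wildtype, {gene: replicates}, truth) where truth has one row
    per gene recording which pairs were perturbed and with what factors.
    """
    gene_specs = gene_specs or {}
    ss = np.random.SeedSequence(seed)
    wt_seed, gene_master = [int(s) % (2**31) for s in ss.generate_state(2, dtype=np.uint64)]
    wildtype = simulate_cohort(template, noise, n=n_wildtype, seed=wt_seed)
    gene_seeds = _spawn_seeds(gene_master, max(len(gene_specs), 1))
    perturbed: dict[str, list[EmbryoRecording]] = {}
    truth_rows = []
    for (gene, spec), gseed in zip(sorted(gene_specs.items()), gene_seeds):
        perturbed[gene] = simulate_cohort(
            template,
            noise,
            n=replicates,
            seed=gseed,
            id_prefix=f"{gene}_r",
            perturbation=spec,
            target_gene=gene,
        )
        truth_rows.append(
            {
                "gene": gene,
                "perturbed_pairs": ";".join(sorted(spec.ads_factor)),
                "ads_factors": ";".join(
                    f"{p}={f:g}" for p, f in sorted(spec.ads_factor.items())
                ),
                "slowdown": spec.slowdown,
                "variance_inflation": ";".join(
                    f"{k}={v:g}" for k, v in sorted(spec.variance_inflation.items())
                ),
                "arrest_frame": spec.arrest_frame,
                "expression_knockout": spec.expression_knockout or "",
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "gene", "perturbed_pairs", "ads_factors", "slowdown",
            "variance_inflation", "arrest_frame", "expression_knockout",
        ],
    )
    return wildtype, perturbed, truth
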
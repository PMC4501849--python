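"""In-memory containers for 4D nuclei-tracking recordings and lineage trees.

An :class:`EmbryoRecording` holds one embryo's curated tracking output: one
row per (cell, frame) with the nucleus position in micrometres and an
optional tissue-marker intensity, plus recording metadata. A
:class:`LineageTree` is the binary pedigree reconstructed from the frame
ranges of the observed cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nomenclature as nom

__all__ = [
    "EmbryoRecording",
    "LineageNode",
    "LineageTree",
    "NucleusObservation",
    "RecordingError",
    "build_lineage",
    "cell_count_at",
]

OBS_COLUMNS = ["cell", "frame", "x", "y", "z", "intensity"]


class RecordingError(ValueError):
    """Raised when a recording violates a structural invariant."""


@dataclass(frozen=True)
class NucleusObservation:
    """A single nucleus at a single 1-based time point, position in um."""

    cell: str
    frame: int
    position: tuple[float, float, float]
    intensity: float | None = None


@dataclass
class EmbryoRecording:
    """One embryo's curated 4D tracking table plus metadata.

    ``observations`` columns: cell, frame, x, y, z, intensity (NaN when the
    recording carries no marker channel). ``normalized`` recordings have been
    re-based so the reference frame is 0 and may hold frame indices <= 0.
    """

    id: str
    observations: pd.DataFrame
    target_gene: str = "wild-type"
    replicate: int = 1
    marker: str = ""
    frame_interval_min: float = 1.5
    last_curated_frame: int = 0
    death_cells: tuple[str, ...] = ()
    normalized: bool = False
    read_report: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        obs = self.observations
        missing = [c for c in ("cell", "frame", "x", "y", "z") if c not in obs.columns]
        if missing:
            raise RecordingError(f"observations missing columns {missing}")
        if "intensity" not in obs.columns:
            obs = obs.assign(intensity=np.nan)
        self.observations = obs[OBS_COLUMNS].reset_index(drop=True)
        if self.last_curated_frame == 0 and len(obs):
            self.last_curated_frame = int(obs["frame"].max())

    # -- structural validation -------------------------------------------------

    def validate(self) -> "EmbryoRecording":
        """Check naming, frame-range and uniqueness invariants; return self."""
        obs = self.observations
        if not len(obs):
            raise RecordingError(f"{self.id}: empty recording")
        bad = [n for n in obs["cell"].unique() if not nom.is_valid_name(n)]
        if bad:
            raise RecordingError(f"{self.id}: invalid cell names {bad[:5]}")
        if not self.normalized and int(obs["frame"].min()) < 1:
            raise RecordingError(f"{self.id}: frame indices must be >= 1")
        dup = obs.duplicated(["cell", "frame"])
        if dup.any():
            rows = obs.index[dup][:5].tolist()
            raise RecordingError(f"{self.id}: duplicate (cell, frame) rows {rows}")
        g = obs.groupby("cell")["frame"]
        span = g.max() - g.min() + 1
        ragged = span[span != g.size()]
        if len(ragged):
            raise RecordingError(
                f"{self.id}: non-contiguous frame range for {ragged.index[:5].tolist()}"
            )
        if int(obs["frame"].max()) > self.last_curated_frame:
            raise RecordingError(
                f"{self.id}: observations extend past last_curated_frame"
            )
        return self

    def cells(self) -> list[str]:
        return self.observations["cell"].unique().tolist()

    def positions_of(self, cell: str) -> pd.DataFrame:
        sel = self.observations[self.observations["cell"] == cell]
        if not len(sel):
            raise KeyError(f"{cell} not observed in recording {self.id}")
        return sel.sort_values("frame").reset_index(drop=True)

    def with_observations(self, obs: pd.DataFrame, **meta) -> "EmbryoRecording":
        return replace(self, observations=obs, **meta)


@dataclass
class LineageNode:
    name: str
    parent: str | None
    daughters: tuple[str, str] | None
    birth_frame: int
    last_frame: int
    died: bool = False
    fate: str | None = None

    @property
    def founder(self) -> str:
        return nom.founder_of(self.name)

    @property
    def generation(self) -> int:
        return nom.generation_of(self.name)

    @property
    def divided(self) -> bool:
        return self.daughters is not None


@dataclass
class LineageTree:
    """Binary pedigree of the observed cells of one recording."""

    nodes: dict[str, LineageNode]
    roots: tuple[str, ...]
    frame_interval_min: float = 1.5
    last_curated_frame: int = 0

    def __getitem__(self, name: str) -> LineageNode:
        return self.nodes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes.values())

    def division_frame(self, name: str) -> int | None:
        """Frame stamped on a cell's division (its daughters' birth frame)."""
        node = self.nodes[name]
        if node.daughters is None:
            return None
        return node.last_frame + 1


def build_lineage(recording: EmbryoRecording) -> LineageTree:
    """Reconstruct the lineage tree from a recording's frame ranges.

    Roots are the cells present at the first observed frame (their mothers
    were never imaged). Every other cell must appear exactly one frame after
    its mother's last observed frame.
    """
    obs = recording.observations
    if not len(obs):
        raise RecordingError(f"{recording.id}: empty recording")
    g = obs.groupby("cell")["frame"]
    birth = g.min().astype(int)
    last = g.max().astype(int)
    first_frame = int(birth.min())
    death_set = set(recording.death_cells)

    daughters: dict[str, list[str]] = {}
    nodes: dict[str, LineageNode] = {}
    roots: list[str] = []
    for name in birth.index:
        if int(birth[name]) == first_frame:
            parent = None
            roots.append(name)
        else:
            parent = nom.mother_of(name)
            if parent not in birth.index:
                raise RecordingError(
                    f"{recording.id}: {name} appears at frame {birth[name]} "
                    f"but its mother {parent} was never observed"
                )
            if int(birth[name]) != int(last[parent]) + 1:
                raise RecordingError(
                    f"{recording.id}: continuity error — {name} appears at frame "
                    f"{birth[name]} but {parent}'s last frame is {last[parent]}"
                )
            daughters.setdefault(parent, []).append(name)
        nodes[name] = LineageNode(
            name=name,
            parent=parent,
            daughters=None,
            birth_frame=int(birth[name]),
            last_frame=int(last[name]),
            died=name in death_set,
        )

    for parent, ds in daughters.items():
        if len(ds) != 2:
            raise RecordingError(
                f"{recording.id}: {parent} has {len(ds)} observed daughters {ds}"
            )
        ds_sorted = tuple(sorted(ds, key=nom.sort_key))
        nodes[parent].daughters = ds_sorted  # type: ignore[assignment]
        if nodes[parent].died:
            raise RecordingError(f"{recording.id}: dead cell {parent} has daughters")

    return LineageTree(
        nodes=nodes,
        roots=tuple(sorted(roots, key=nom.sort_key)),
        frame_interval_min=recording.frame_interval_min,
        last_curated_frame=recording.last_curated_frame,
    )


def cell_count_at(recording: EmbryoRecording, frame: int) -> int:
    """Number of distinct cells observed at one frame."""
    lo = int(recording.observations["frame"].min())
    if not (lo <= frame <= recording.last_curated_frame):
        raise ValueError(
            f"frame {frame} outside observed range [{lo}, {recording.last_curated_frame}]"
        )
    obs = recording.observations
    return int((obs["frame"] == frame).sum())
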
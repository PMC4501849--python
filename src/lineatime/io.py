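"""Readers and writers for nuclei tables, cohort manifests and newick trees.

The nuclei-table format is the curated AceTree-style export this pipeline
consumes: delimited text with a header row and columns
``cell, frame, x, y, z[, intensity]``. Positions on disk are in pixel /
z-plane units; the dialect supplies the micrometre scale factors so all
in-memory geometry is isotropic micrometres.
"""

from __future__ import annotations

import csv
import io as _io
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import nomenclature as nom
from .model import EmbryoRecording, LineageTree, RecordingError

__all__ = [
    "TableDialect",
    "read_manifest",
    "read_nuclei_table",
    "to_newick",
    "write_manifest",
    "write_nuclei_table",
]


@dataclass
class TableDialect:
    """How to parse a nuclei table and scale its coordinates.

    ``z_um_per_plane`` defaults to the 0.71 um confocal plane spacing of the
    recordings this format comes from; ``xy_um_per_pixel`` defaults to 1.
    ``drop_patterns`` are regexes for non-lineage names (polar bodies,
    segmentation artifacts) that are silently dropped and counted.
    """

    delimiter: str | None = None  # None -> sniff from header line
    xy_um_per_pixel: float = 1.0
    z_um_per_plane: float = 0.71
    drop_patterns: tuple[str, ...] = (r"^Nuc", r"polar")

    def _dropper(self) -> re.Pattern:
        return re.compile("|".join(f"(?:{p})" for p in self.drop_patterns))


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    try:
        return csv.Sniffer().sniff(header, delimiters=",\t;").delimiter
    except csv.Error:
        return "\t" if "\t" in header else ","


def read_nuclei_table(
    path: str | Path,
    dialect: TableDialect | None = None,
    **meta,
) -> EmbryoRecording:
    """Read one embryo's nuclei table into a validated recording.

    Keyword ``meta`` fields (id, target_gene, replicate, marker,
    frame_interval_min, death_cells) populate the recording metadata; ``id``
    defaults to the file stem.
    """
    path = Path(path)
    dialect = dialect or TableDialect()
    sep = dialect.delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    if "time" in df.columns and "frame" not in df.columns:
        df = df.rename(columns={"time": "frame"})
    required = ["cell", "frame", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RecordingError(f"{path}: missing required column(s) {missing}")

    df["cell"] = df["cell"].astype(str).str.strip()
    dropper = dialect._dropper()
    is_valid = df["cell"].map(nom.is_valid_name)
    droppable = df["cell"].str.contains(dropper) & ~is_valid
    bad = df.loc[~is_valid & ~droppable, "cell"].unique().tolist()
    if bad:
        rows = df.index[df["cell"].isin(bad)][:5].tolist()
        raise RecordingError(f"{path}: invalid cell names {bad[:5]} at rows {rows}")
    n_dropped = int(droppable.sum())
    df = df[~droppable].copy()

    df["frame"] = df["frame"].astype(int)
    df["x"] = df["x"].astype(float) * dialect.xy_um_per_pixel
    df["y"] = df["y"].astype(float) * dialect.xy_um_per_pixel
    df["z"] = df["z"].astype(float) * dialect.z_um_per_plane
    if "intensity" not in df.columns:
        df["intensity"] = np.nan

    rec = EmbryoRecording(
        id=meta.pop("id", path.stem),
        observations=df[["cell", "frame", "x", "y", "z", "intensity"]],
        **meta,
    )
    rec.read_report = {"rows": len(df), "dropped_non_lineage_rows": n_dropped}
    return rec.validate()


def write_nuclei_table(
    recording: EmbryoRecording,
    path: str | Path,
    dialect: TableDialect | None = None,
) -> Path:
    """Write a recording back to disk in the on-disk (pixel/plane) units."""
    path = Path(path)
    dialect = dialect or TableDialect()
    sep = dialect.delimiter or ("\t" if path.suffix in (".tsv", ".txt") else ",")
    out = recording.observations.copy()
    out["x"] = out["x"] / dialect.xy_um_per_pixel
    out["y"] = out["y"] / dialect.xy_um_per_pixel
    out["z"] = out["z"] / dialect.z_um_per_plane
    cols = ["cell", "frame", "x", "y", "z"]
    if out["intensity"].notna().any():
        cols.append("intensity")
    out[cols].to_csv(path, sep=sep, index=False, float_format="%.6g")
    return path


# -- manifest ------------------------------------------------------------------

MANIFEST_COLUMNS = ["recording_id", "path", "target_gene", "replicate", "marker"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise RecordingError(f"{path}: manifest missing column(s) {missing}")
    df["replicate"] = df["replicate"].astype(int)
    return df[MANIFEST_COLUMNS]


def write_manifest(rows: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    rows[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


# -- newick --------------------------------------------------------------------

def to_newick(
    tree: LineageTree,
    censored_length: str = "observed",
) -> str:
    """Serialize a lineage tree as newick with branch lengths in minutes.

    Divided cells get their cycle length; undivided (censored) leaves get
    either their observed lifespan (``"observed"``, default) or ``0``
    (``"zero"``).
    """
    if censored_length not in ("observed", "zero"):
        raise ValueError("censored_length must be 'observed' or 'zero'")
    dt = tree.frame_interval_min

    def branch_length(name: str) -> float:
        node = tree[name]
        if node.divided:
            return (node.last_frame + 1 - node.birth_frame) * dt
        if censored_length == "zero":
            return 0.0
        return (node.last_frame - node.birth_frame + 1) * dt

    buf = _io.StringIO()

    def emit(name: str) -> None:
        node = tree[name]
        if node.divided:
            buf.write("(")
            emit(node.daughters[0])  # type: ignore[index]
            buf.write(",")
            emit(node.daughters[1])  # type: ignore[index]
            buf.write(")")
        buf.write(f"{name}:{branch_length(name):g}")

    if len(tree.roots) == 1:
        emit(tree.roots[0])
    else:
        buf.write("(")
        for i, root in enumerate(tree.roots):
            if i:
                buf.write(",")
            emit(root)
        buf.write(")P0:0")
    buf.write(";")
    return buf.getvalue()
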
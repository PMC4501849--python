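"""Sulston cell-name logic for the C. elegans embryonic lineage.

Cell names follow Sulston's convention: a founder stem (AB, MS, E, C, D)
followed by letters from {a, p, l, r, d, v} recording the daughter's side of
each successive division, plus the special early names P0-P4, EMS, Z2, Z3
whose mother/daughter relationships do not follow the suffix rule.
"""

from __future__ import annotations

from functools import lru_cache

__all__ = [
    "AXIS_LETTERS",
    "EARLY_ROUND_CELLS",
    "FOUNDERS",
    "daughters_of",
    "founder_of",
    "generation_of",
    "is_ancestor",
    "is_valid_name",
    "mother_of",
    "sister_of",
    "sort_key",
    "validate_name",
]

AXIS_LETTERS = "aplrdv"

#: daughters whose names are not formed by appending an axis letter
SPECIAL_DAUGHTERS: dict[str, tuple[str, str]] = {
    "P0": ("AB", "P1"),
    "AB": ("ABa", "ABp"),
    "P1": ("EMS", "P2"),
    "EMS": ("MS", "E"),
    "P2": ("C", "P3"),
    "P3": ("D", "P4"),
    "P4": ("Z2", "Z3"),
}

SPECIAL_MOTHERS: dict[str, str] = {
    d: m for m, ds in SPECIAL_DAUGHTERS.items() for d in ds
}

#: stems that accept axis-letter suffixes
SUFFIX_STEMS = ("AB", "MS", "E", "C", "D")

#: names whose division timings span the first two rounds and are excluded
EARLY_ROUND_CELLS = frozenset({"AB", "P1", "ABa", "ABp", "EMS", "P2"})

#: founder blastomeres that define sublineages
FOUNDERS = ("ABa", "ABp", "MS", "E", "C", "D", "P4")

_SPECIAL_NAMES = frozenset(SPECIAL_MOTHERS) | {"P0"}

# rank of suffix letters for deterministic ordering: the anterior/left/dorsal
# letter of each axis pair sorts first
_LETTER_RANK = {c: i for i, c in enumerate(AXIS_LETTERS)}


class NameError_(ValueError):
    """Raised for malformed or unknown Sulston names."""


def _split(name: str) -> tuple[str, str] | None:
    """Return (stem, suffix) for a generic suffixed name, else None."""
    for stem in SUFFIX_STEMS:
        if name.startswith(stem):
            suffix = name[len(stem):]
            if all(c in AXIS_LETTERS for c in suffix):
                return stem, suffix
    return None


@lru_cache(maxsize=None)
def is_valid_name(name: str) -> bool:
    """True if *name* is a well-formed Sulston or early-embryo cell name."""
    if not name or not isinstance(name, str):
        return False
    if name in _SPECIAL_NAMES:
        return True
    parts = _split(name)
    # bare "E" etc. (empty suffix) are founders, also valid
    return parts is not None


def validate_name(name: str) -> str:
    if not is_valid_name(name):
        raise NameError_(f"not a valid Sulston cell name: {name!r}")
    return name


@lru_cache(maxsize=None)
def mother_of(name: str) -> str:
    """Name of the mother cell.

    Early divisions follow the special founder table (e.g. ``E`` -> ``EMS``,
    ``P4`` -> ``P3``, making D and P4 sisters); every other name sheds its
    final axis letter.
    """
    validate_name(name)
    if name == "P0":
        raise NameError_("P0 is the zygote and has no mother")
    if name in SPECIAL_MOTHERS:
        return SPECIAL_MOTHERS[name]
    stem, suffix = _split(name)  # type: ignore[misc]
    if not suffix:
        raise NameError_(f"{name!r} has no mother outside the founder table")
    return name[:-1]


@lru_cache(maxsize=None)
def daughters_of(name: str, axis: str = "ap") -> tuple[str, str]:
    """Names of the two daughters.

    Special early cells use the founder table; generic cells append the two
    letters of *axis* (one of ``"ap"``, ``"lr"``, ``"dv"``).
    """
    validate_name(name)
    if name in SPECIAL_DAUGHTERS:
        return SPECIAL_DAUGHTERS[name]
    if name in ("Z2", "Z3"):
        raise NameError_(f"{name} does not divide during embryogenesis")
    if len(axis) != 2 or any(c not in AXIS_LETTERS for c in axis):
        raise NameError_(f"invalid division axis {axis!r}")
    return name + axis[0], name + axis[1]


def sister_of(name: str) -> str:
    """The other daughter of this cell's mother."""
    d1, d2 = daughters_of(mother_of(name), axis=_axis_of(name))
    return d2 if name == d1 else d1


def _axis_of(name: str) -> str:
    """Axis pair containing this generic cell's final letter (default a/p)."""
    if name in SPECIAL_MOTHERS or name == "P0":
        return "ap"
    last = name[-1]
    for pair in ("ap", "lr", "dv"):
        if last in pair:
            return pair
    return "ap"


_SPECIAL_GENERATION = {
    "P0": 0, "AB": 1, "P1": 1,
    "ABa": 2, "ABp": 2, "EMS": 2, "P2": 2,
    "MS": 3, "E": 3, "C": 3, "P3": 3,
    "D": 4, "P4": 4, "Z2": 5, "Z3": 5,
}


@lru_cache(maxsize=None)
def generation_of(name: str) -> int:
    """Number of divisions separating this cell from the zygote P0."""
    validate_name(name)
    if name in _SPECIAL_GENERATION:
        return _SPECIAL_GENERATION[name]
    stem, suffix = _split(name)  # type: ignore[misc]
    return _SPECIAL_GENERATION[stem if stem != "AB" else "AB"] + len(suffix)


@lru_cache(maxsize=None)
def founder_of(name: str) -> str:
    """The founder blastomere whose sublineage contains this cell.

    For cells at or above the founder generation the name itself is returned
    (e.g. ``founder_of("EMS") == "EMS"``).
    """
    validate_name(name)
    cur = name
    while cur not in FOUNDERS:
        if cur in ("P0", "AB", "P1", "EMS", "P2", "P3"):
            return cur
        cur = mother_of(cur)
    return cur


@lru_cache(maxsize=None)
def is_ancestor(ancestor: str, name: str) -> bool:
    """True if *ancestor* equals *name* or lies on its mother chain."""
    validate_name(ancestor)
    cur = validate_name(name)
    while True:
        if cur == ancestor:
            return True
        if cur == "P0":
            return False
        cur = mother_of(cur)


def sort_key(name: str) -> tuple:
    """Deterministic ordering key: generation, then lineal position.

    Within a sister pair the anterior/left/dorsal daughter (or the first
    entry of the founder table) sorts first.
    """
    validate_name(name)
    path: list[int] = []
    cur = name
    while cur != "P0":
        m = mother_of(cur)
        if cur in SPECIAL_MOTHERS:
            path.append(SPECIAL_DAUGHTERS[m].index(cur))
        else:
            path.append(_LETTER_RANK[cur[-1]] % 2)
        cur = m
    return (generation_of(name), tuple(reversed(path)))
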
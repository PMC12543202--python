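"""Paired up/down marker-set catalogs for germinal-center substages.

A catalog holds, for each GC substage, one set of upregulated and one set
of downregulated marker genes.  Pairing is total: a substage without both
directions is rejected.  Catalogs round-trip through GMT, the community
standard for gene-set exchange; because GMT has no native pairing concept,
the pairing is encoded in the set name as ``<substage><delim><direction>``
(default delimiter ``__``, e.g. ``DZ_a__up``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

DIRECTIONS = ("up", "down")
DEFAULT_DELIM = "__"


@dataclass(frozen=True)
class MarkerSet:
    """One direction of one substage's signature.

    Parameters
    ----------
    substage : str
        Substage name (e.g. ``"DZ_a"``).
    direction : {"up", "down"}
        Whether these genes mark up- or downregulation in the substage.
    genes : tuple of str
        Ordered, duplicate-free gene identifiers. Identifiers are opaque
        strings; symbol/Ensembl mapping is the caller's concern.
    """

    substage: str
    direction: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")
        if len(self.genes) == 0:
            raise ValueError(f"marker set {self.substage}/{self.direction} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate genes in set {self.substage}/{self.direction}")
        object.__setattr__(self, "genes", tuple(self.genes))

    def name(self, delim: str = DEFAULT_DELIM) -> str:
        return f"{self.substage}{delim}{self.direction}"


@dataclass
class MarkerCatalog:
    """Ordered collection of paired marker sets.

    Invariants: substage names are unique and every substage has exactly
    one "up" and one "down" set.
    """

    sets: list[MarkerSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: dict[tuple[str, str], int] = {}
        for s in self.sets:
            key = (s.substage, s.direction)
            if key in seen:
                raise ValueError(f"duplicate set {s.substage}/{s.direction}")
            seen[key] = 1
        by_sub: dict[str, set[str]] = {}
        for s in self.sets:
            by_sub.setdefault(s.substage, set()).add(s.direction)
        for sub, dirs in by_sub.items():
            missing = set(DIRECTIONS) - dirs
            if missing:
                raise ValueError(
                    f"substage {sub!r} is unpaired: missing direction(s) {sorted(missing)}"
                )

    @property
    def substages(self) -> list[str]:
        """Substage names in first-appearance order."""
        out: list[str] = []
        for s in self.sets:
            if s.substage not in out:
                out.append(s.substage)
        return out

    @property
    def n_substages(self) -> int:
        return len(self.substages)

    def get(self, substage: str, direction: str) -> MarkerSet:
        for s in self.sets:
            if s.substage == substage and s.direction == direction:
                return s
        raise KeyError(f"no set {substage}/{direction} in catalog")

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets:
            out.update(s.genes)
        return out

    def __len__(self) -> int:
        return len(self.sets)


def write_gmt(catalog: MarkerCatalog, path: str | Path, delim: str = DEFAULT_DELIM) -> None:
    """Serialize as GMT: one tab-separated line per set (name, description, genes)."""
    lines = []
    for s in catalog.sets:
        desc = f"{s.substage} {s.direction}regulated markers"
        lines.append("\t".join([s.name(delim), desc, *s.genes]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_gmt(path: str | Path, delim: str = DEFAULT_DELIM) -> MarkerCatalog:
    """Parse a GMT file into a paired catalog.

    Set names must follow ``<substage><delim><up|down>``.  Malformed lines,
    duplicate set names and unpaired substages raise ``ValueError`` with
    the offending line number or substage.
    """
    sets: list[MarkerSet] = []
    seen_names: set[str] = set()
    text = Path(path).read_text(encoding="utf-8")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 tab-separated fields")
        name, _desc, *genes = fields
        if name in seen_names:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        seen_names.add(name)
        if delim not in name:
            raise ValueError(
                f"{path}:{lineno}: set name {name!r} lacks the {delim!r} direction suffix"
            )
        substage, _, direction = name.rpartition(delim)
        if direction not in DIRECTIONS:
            raise ValueError(
                f"{path}:{lineno}: set name {name!r} must end in "
                f"{delim}up or {delim}down"
            )
        genes = [g for g in genes if g]
        sets.append(MarkerSet(substage=substage, direction=direction, genes=tuple(genes)))
    return MarkerCatalog(sets=sets)  # __post_init__ enforces pairing


def restrict_to_universe(
    catalog: MarkerCatalog,
    universe: Iterable[str],
    min_set_size: int = 5,
) -> tuple[MarkerCatalog, dict]:
    """Intersect every set with the measured gene universe.

    Substages where either direction's intersection falls below
    ``min_set_size`` are dropped and recorded in the report.  Gene and
    substage order are preserved.  Idempotent.

    Parameters
    ----------
    universe : iterable of str
        Measured gene ids; an ``ExprMatrix`` DataFrame may be passed
        directly (its index is used).

    Returns
    -------
    (MarkerCatalog, dict)
        The restricted catalog and a report with per-set retained sizes
        and the dropped substages.
    """
    if min_set_size < 1:
        raise ValueError("min_set_size must be >= 1")
    if hasattr(universe, "index"):
        universe = universe.index
    uni = set(universe)

    kept_sizes: dict[str, int] = {}
    dropped: dict[str, dict] = {}
    new_sets: list[MarkerSet] = []
    for sub in catalog.substages:
        pair = {d: catalog.get(sub, d) for d in DIRECTIONS}
        inter = {d: tuple(g for g in pair[d].genes if g in uni) for d in DIRECTIONS}
        if any(len(inter[d]) < min_set_size for d in DIRECTIONS):
            dropped[sub] = {d: len(inter[d]) for d in DIRECTIONS}
            continue
        for d in DIRECTIONS:
            kept_sizes[f"{sub}{DEFAULT_DELIM}{d}"] = len(inter[d])
            new_sets.append(MarkerSet(substage=sub, direction=d, genes=inter[d]))
    if not new_sets:
        raise ValueError(
            f"all {catalog.n_substages} substages dropped: no direction retained "
            f">= {min_set_size} measured genes"
        )
    report = {
        "min_set_size": min_set_size,
        "kept_set_sizes": kept_sizes,
        "dropped_substages": dropped,
    }
    return MarkerCatalog(sets=new_sets), report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n", encoding="utf-8")
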
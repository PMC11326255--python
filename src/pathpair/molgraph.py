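"""Hydrogen-free molecular graphs parsed from MDL molfiles (V2000).

Metabolite structures are exchanged as MDL molfiles, one per compound.
For substructure-count featurization only the heavy-atom skeleton matters,
so explicit hydrogens are stripped at parse time and the remaining atoms
are re-indexed contiguously.  Bond orders are kept verbatim (1=single,
2=double, 3=triple, 4=aromatic); no kekulization or aromaticity perception
is performed, so parsing is fully deterministic.  Charges, isotopes and
stereo flags are ignored, and disconnected components (e.g. salts) are
retained as a single graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

VALID_BOND_ORDERS = frozenset({1, 2, 3, 4})


class MolfileParseError(ValueError):
    """Structured parse failure naming the offending metabolite."""

    def __init__(self, message: str, metabolite_id: str | None = None):
        self.metabolite_id = metabolite_id
        super().__init__(f"{metabolite_id or '<unknown>'}: {message}")


@dataclass(frozen=True)
class MolecularGraph:
    """An element-labeled graph of non-hydrogen atoms and typed bonds.

    Bonds are stored as ``(a, b, order)`` with ``a < b`` and no duplicate
    unordered pairs; indices refer to positions in ``atoms``.
    """

    metabolite_id: str
    atoms: tuple[str, ...]
    bonds: tuple[tuple[int, int, int], ...]

    @property
    def atom_count(self) -> int:
        return len(self.atoms)

    @property
    def bond_count(self) -> int:
        return len(self.bonds)

    def __post_init__(self) -> None:
        if self.atom_count < 1:
            raise MolfileParseError("graph has no non-hydrogen atoms", self.metabolite_id)
        if any(el == "H" for el in self.atoms):
            raise MolfileParseError("hydrogen atom present after stripping", self.metabolite_id)
        seen: set[tuple[int, int]] = set()
        n = self.atom_count
        for a, b, order in self.bonds:
            if not (0 <= a < n and 0 <= b < n):
                raise MolfileParseError(f"bond ({a},{b}) index out of range", self.metabolite_id)
            if a == b:
                raise MolfileParseError(f"self-bond on atom {a}", self.metabolite_id)
            if a > b:
                raise MolfileParseError(f"bond ({a},{b}) not in canonical order", self.metabolite_id)
            if (a, b) in seen:
                raise MolfileParseError(f"duplicate bond ({a},{b})", self.metabolite_id)
            if order not in VALID_BOND_ORDERS:
                raise MolfileParseError(f"unsupported bond order {order}", self.metabolite_id)
            seen.add((a, b))


def _canonical_bonds(bonds: Iterable[tuple[int, int, int]]) -> tuple[tuple[int, int, int], ...]:
    return tuple(sorted((min(a, b), max(a, b), order) for a, b, order in bonds))


def strip_hydrogens(
    metabolite_id: str,
    atoms: Iterable[str],
    bonds: Iterable[tuple[int, int, int]],
) -> MolecularGraph:
    """Drop H atoms and their incident bonds, re-indexing the remainder.

    Idempotent: applying it to an already hydrogen-free graph returns an
    identical graph.
    """
    atoms = list(atoms)
    keep = [i for i, el in enumerate(atoms) if el != "H"]
    if not keep:
        raise MolfileParseError("molecule contains only hydrogen atoms", metabolite_id)
    remap = {old: new for new, old in enumerate(keep)}
    new_bonds = [
        (remap[a], remap[b], order)
        for a, b, order in bonds
        if a in remap and b in remap
    ]
    return MolecularGraph(
        metabolite_id=metabolite_id,
        atoms=tuple(atoms[i] for i in keep),
        bonds=_canonical_bonds(new_bonds),
    )


def parse_molfile(text: str, metabolite_id: str | None = None) -> MolecularGraph:
    """Parse a V2000 molfile string into a hydrogen-free :class:`MolecularGraph`.

    ``metabolite_id`` defaults to the molfile title line when present.
    V3000 input raises an explicit unsupported-format error.
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise MolfileParseError("molfile shorter than header + counts line", metabolite_id)
    if metabolite_id is None:
        metabolite_id = lines[0].strip() or None
    counts = lines[3]
    if "V3000" in counts:
        raise MolfileParseError("V3000 molfiles are not supported", metabolite_id)
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError) as exc:
        raise MolfileParseError(f"malformed counts line: {counts!r}", metabolite_id) from exc
    if n_atoms < 1:
        raise MolfileParseError("counts line declares zero atoms", metabolite_id)
    if len(lines) < 4 + n_atoms + n_bonds:
        raise MolfileParseError("atom/bond block truncated", metabolite_id)

    atoms: list[str] = []
    for i in range(n_atoms):
        line = lines[4 + i]
        symbol = line[31:34].strip() if len(line) >= 32 else ""
        if not symbol:
            parts = line.split()
            if len(parts) < 4:
                raise MolfileParseError(f"malformed atom line {i + 1}: {line!r}", metabolite_id)
            symbol = parts[3]
        atoms.append(symbol)

    bonds: list[tuple[int, int, int]] = []
    for i in range(n_bonds):
        line = lines[4 + n_atoms + i]
        try:
            a = int(line[0:3]) - 1
            b = int(line[3:6]) - 1
            order = int(line[6:9])
        except (ValueError, IndexError) as exc:
            raise MolfileParseError(f"malformed bond line {i + 1}: {line!r}", metabolite_id) from exc
        if not (0 <= a < n_atoms and 0 <= b < n_atoms):
            raise MolfileParseError(
                f"bond line {i + 1} references atom out of range: {line!r}", metabolite_id
            )
        bonds.append((a, b, order))

    return strip_hydrogens(metabolite_id or "<unknown>", atoms, bonds)


def write_molfile(graph: MolecularGraph, title: str | None = None) -> str:
    """Serialize a graph to a minimal V2000 molfile (all coordinates zero)."""
    lines = [
        title if title is not None else graph.metabolite_id,
        "  pathpair",
        "",
        f"{graph.atom_count:3d}{graph.bond_count:3d}  0  0  0  0  0  0  0  0999 V2000",
    ]
    for el in graph.atoms:
        lines.append(f"{0.0:10.4f}{0.0:10.4f}{0.0:10.4f} {el:<3}0  0  0  0  0  0  0  0  0  0  0  0")
    for a, b, order in graph.bonds:
        lines.append(f"{a + 1:3d}{b + 1:3d}{order:3d}  0")
    lines.append("M  END")
    return "\n".join(lines) + "\n"


def read_molfile_dir(directory: str | Path) -> dict[str, MolecularGraph]:
    """Parse every ``*.mol`` file in a directory, keyed by file stem.

    Entries that fail to parse (e.g. hydrogen-only or malformed records)
    are skipped with a logged warning rather than aborting the corpus.
    """
    directory = Path(directory)
    graphs: dict[str, MolecularGraph] = {}
    for path in sorted(directory.glob("*.mol")):
        try:
            graphs[path.stem] = parse_molfile(path.read_text(), metabolite_id=path.stem)
        except MolfileParseError as exc:
            logger.warning("skipping %s: %s", path.name, exc)
    if not graphs:
        raise MolfileParseError(f"no parseable molfiles in {directory}")
    return graphs


# -- canonical internal TSV persistence --------------------------------------

def write_graphs_tsv(
    graphs: Mapping[str, MolecularGraph],
    atoms_path: str | Path,
    bonds_path: str | Path,
) -> None:
    """Persist graphs as two headered TSVs (one row per atom / per bond)."""
    atom_rows = []
    bond_rows = []
    for mid in sorted(graphs):
        g = graphs[mid]
        for i, el in enumerate(g.atoms):
            atom_rows.append((mid, i, el))
        for a, b, order in g.bonds:
            bond_rows.append((mid, a, b, order))
    pd.DataFrame(atom_rows, columns=["metabolite_id", "atom_index", "element"]).to_csv(
        atoms_path, sep="\t", index=False
    )
    pd.DataFrame(bond_rows, columns=["metabolite_id", "atom_a", "atom_b", "bond_order"]).to_csv(
        bonds_path, sep="\t", index=False
    )


def read_graphs_tsv(atoms_path: str | Path, bonds_path: str | Path) -> dict[str, MolecularGraph]:
    """Inverse of :func:`write_graphs_tsv`; round-trips exactly."""
    atoms_df = pd.read_csv(atoms_path, sep="\t", dtype={"metabolite_id": str})
    bonds_df = pd.read_csv(bonds_path, sep="\t", dtype={"metabolite_id": str})
    graphs: dict[str, MolecularGraph] = {}
    bonds_by_id = dict(tuple(bonds_df.groupby("metabolite_id", sort=False)))
    for mid, grp in atoms_df.groupby("metabolite_id", sort=False):
        grp = grp.sort_values("atom_index")
        if list(grp["atom_index"]) != list(range(len(grp))):
            raise MolfileParseError("non-contiguous atom indices in TSV", str(mid))
        bg = bonds_by_id.get(mid)
        bonds = (
            [(int(a), int(b), int(o)) for a, b, o in bg[["atom_a", "atom_b", "bond_order"]].itertuples(index=False)]
            if bg is not None
            else []
        )
        graphs[str(mid)] = MolecularGraph(
            metabolite_id=str(mid),
            atoms=tuple(grp["element"]),
            bonds=_canonical_bonds(bonds),
        )
    return graphs
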
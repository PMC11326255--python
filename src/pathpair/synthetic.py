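"""Synthetic molfile corpora and pathway universes with planted chemical signal.

The generator emulates the statistical shape of a curated pathway
knowledgebase at desk scale: random small molecular graphs with a realistic
element mix, a two-level pathway hierarchy (individual pathways at L3,
disjoint unions of them as L2 categories), and right-skewed pathway sizes
drawn from a truncated log-normal with a minimum of three members.  The L3
pathways partition the metabolite pool, so each metabolite belongs to one
pathway and its parent category.  Each L3
pathway owns a distinct small *motif* (an element-and-bond-order labeled
path) and a characteristic element bias (member skeletons over-sample one
element, the way nucleotide pathways are nitrogen-rich or lipid pathways
carbon-rich); a member metabolite carries both with probability
``signal_strength``, which plants a learnable shared-substructure signal:
the composition bias gives a first-order membership cue and the motif an
exact one.
With ``size_dependent_signal`` the carry probability additionally grows
with pathway size rank, making larger pathways easier to predict.

Everything is driven by a single seeded generator, so an identical config
and seed reproduce a byte-identical corpus on disk.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .molgraph import MolecularGraph, write_molfile

DEFAULT_ELEMENTS = (("C", 0.70), ("N", 0.12), ("O", 0.12), ("S", 0.04), ("P", 0.02))
DEFAULT_BOND_ORDERS = ((1, 0.80), (2, 0.15), (3, 0.03), (4, 0.02))


@dataclass(frozen=True)
class Motif:
    """A small labeled path graph planted as a shared substructure."""

    elements: tuple[str, ...]
    bond_orders: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.elements) < 1 or len(self.bond_orders) != len(self.elements) - 1:
            raise ValueError("motif must be a path: n elements, n-1 bond orders")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic universe."""

    n_metabolites: int = 500
    n_pathways_l3: int = 20
    n_pathways_l2: int = 4
    atoms_range: tuple[int, int] = (3, 5)
    elements: tuple[tuple[str, float], ...] = DEFAULT_ELEMENTS
    bond_orders: tuple[tuple[int, float], ...] = DEFAULT_BOND_ORDERS
    extra_edge_prob: float = 0.10
    motif_size: int = 3
    element_tilt: float = 6.0
    signal_strength: float = 1.0
    pathway_size_median: float = 25.0
    pathway_size_sigma: float = 0.7
    min_pathway_size: int = 3
    size_dependent_signal: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_metabolites, self.n_pathways_l3, self.n_pathways_l2, self.motif_size) < 1:
            raise ValueError("all sizes must be >= 1")
        if not 0 <= self.signal_strength <= 1:
            raise ValueError("signal_strength must lie in [0, 1]")
        if self.atoms_range[0] < 1 or self.atoms_range[0] > self.atoms_range[1]:
            raise ValueError("invalid atoms_range")
        if self.n_pathways_l2 > self.n_pathways_l3:
            raise ValueError("cannot have more L2 categories than L3 pathways")
        if self.min_pathway_size < 1 or self.min_pathway_size > self.n_metabolites:
            raise ValueError("invalid min_pathway_size")


def default_motif_library(n_motifs: int, motif_size: int = 3) -> list[Motif]:
    """Deterministically pick ``n_motifs`` distinct path motifs.

    Candidate motifs (every element sequence x bond-order sequence) are
    ranked by their probability under the background element/bond-order
    distribution, rarest first, so planted motifs are substructures the
    random skeletons essentially never produce by chance.  The ranking is
    a fixed deterministic order: motif k is the same in every run.
    """
    el_w = dict(DEFAULT_ELEMENTS)
    bo_w = dict(DEFAULT_BOND_ORDERS)
    candidates = []
    for els in itertools.product(sorted(el_w), repeat=motif_size):
        for bos in itertools.product(sorted(bo_w), repeat=motif_size - 1):
            prob = math.prod(el_w[e] for e in els) * math.prod(bo_w[o] for o in bos)
            candidates.append((prob, els, bos))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    # Two path motifs that are mirror images of each other (or agree on the
    # middle atom's bonded neighborhood) collide in color space; keep only
    # candidates whose middle-atom radius-1 color is new so every pathway
    # gets a marker color no other pathway produces.
    motifs: list[Motif] = []
    seen_markers: set[str] = set()
    for _, els, bos in candidates:
        mid = motif_size // 2
        neighbors = []
        if mid > 0:
            neighbors.append(f"{bos[mid - 1]}:{els[mid - 1]}")
        if mid < motif_size - 1:
            neighbors.append(f"{bos[mid]}:{els[mid + 1]}")
        marker = f"{els[mid]}(" + ",".join(sorted(neighbors)) + ")"
        if marker in seen_markers:
            continue
        seen_markers.add(marker)
        motifs.append(Motif(tuple(els), tuple(bos)))
        if len(motifs) == n_motifs:
            return motifs
    raise ValueError("motif library exhausted; increase motif_size")


def generate_molecule(
    config: GeneratorConfig,
    metabolite_id: str,
    motifs: list[Motif],
    rng: np.random.Generator,
    tilt_elements: list[tuple[str, float]] | None = None,
) -> tuple[MolecularGraph, str]:
    """One connected random molecular graph with the given motifs embedded.

    The base skeleton is a random spanning tree over sampled elements with
    occasional extra edges; each motif is appended as a labeled path wired
    to a random base atom by a single bond, so the motif survives parsing
    as an exact labeled subgraph.  ``tilt_elements`` is a list of
    (element, multiplier) pairs applied to the sampling weights, shifting
    the molecule's overall composition toward its pathways' characteristic
    chemistry.
    """
    n_base = int(rng.integers(config.atoms_range[0], config.atoms_range[1] + 1))
    for motif in motifs:
        if motif.n_atoms > n_base:
            raise ValueError(
                f"{metabolite_id}: motif with {motif.n_atoms} atoms exceeds the "
                f"{n_base}-atom base molecule"
            )
    el_symbols = [e for e, _ in config.elements]
    el_weights = np.array([w for _, w in config.elements], dtype=float)
    for el, multiplier in tilt_elements or ():
        el_weights[el_symbols.index(el)] *= multiplier
    el_weights /= el_weights.sum()
    bo_values = [o for o, _ in config.bond_orders]
    bo_weights = np.array([w for _, w in config.bond_orders], dtype=float)
    bo_weights /= bo_weights.sum()

    atoms = [el_symbols[i] for i in rng.choice(len(el_symbols), size=n_base, p=el_weights)]
    bonds: set[tuple[int, int]] = set()
    orders: dict[tuple[int, int], int] = {}

    def add_bond(a: int, b: int, order: int) -> None:
        key = (min(a, b), max(a, b))
        if key not in bonds and a != b:
            bonds.add(key)
            orders[key] = order

    for i in range(1, n_base):
        parent = int(rng.integers(0, i))
        add_bond(parent, i, bo_values[int(rng.choice(len(bo_values), p=bo_weights))])
    if n_base > 2:
        n_extra = rng.binomial(n_base, config.extra_edge_prob)
        for _ in range(n_extra):
            a, b = rng.choice(n_base, size=2, replace=False)
            add_bond(int(a), int(b), bo_values[int(rng.choice(len(bo_values), p=bo_weights))])

    for motif in motifs:
        attach = int(rng.integers(0, n_base))
        start = len(atoms)
        atoms.extend(motif.elements)
        add_bond(attach, start, 1)
        for k, order in enumerate(motif.bond_orders):
            add_bond(start + k, start + k + 1, order)

    graph = MolecularGraph(
        metabolite_id=metabolite_id,
        atoms=tuple(atoms),
        bonds=tuple(sorted((a, b, orders[(a, b)]) for a, b in bonds)),
    )
    return graph, write_molfile(graph)


def _pathway_sizes(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Right-skewed pathway sizes that partition the metabolite pool.

    Log-normal draws fix the relative sizes; they are then rescaled so the
    sizes sum to ``n_metabolites`` exactly, with every pathway keeping at
    least ``min_pathway_size`` members.
    """
    if config.n_pathways_l3 * config.min_pathway_size > config.n_metabolites:
        raise ValueError(
            "infeasible size distribution: "
            f"{config.n_pathways_l3} pathways x min size {config.min_pathway_size} "
            f"exceeds {config.n_metabolites} metabolites"
        )
    raw = rng.lognormal(
        mean=math.log(config.pathway_size_median),
        sigma=config.pathway_size_sigma,
        size=config.n_pathways_l3,
    )
    sizes = np.maximum(
        np.round(raw / raw.sum() * config.n_metabolites).astype(int),
        config.min_pathway_size,
    )
    # repair rounding drift on the largest pathways, respecting the minimum
    order = np.argsort(-sizes)
    i = 0
    while sizes.sum() != config.n_metabolites:
        j = order[i % len(order)]
        if sizes.sum() > config.n_metabolites:
            if sizes[j] > config.min_pathway_size:
                sizes[j] -= 1
        else:
            sizes[j] += 1
        i += 1
    return sizes


def generate_universe(config: GeneratorConfig, out_dir: str | Path) -> dict:
    """Write a molfile directory, membership TSV and ground-truth manifest.

    L3 pathways draw their members uniformly from the metabolite pool and
    get distinct motifs; L2 categories are unions of disjoint round-robin
    groups of L3 pathways, inheriting their members.  Returns the manifest
    (also written as ``manifest.json``).
    """
    out_dir = Path(out_dir)
    mol_dir = out_dir / "molfiles"
    mol_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    met_ids = [f"M{i:05d}" for i in range(config.n_metabolites)]
    l3_ids = [f"P3_{k:03d}" for k in range(config.n_pathways_l3)]
    motifs = default_motif_library(config.n_pathways_l3, config.motif_size)
    sizes = _pathway_sizes(config, rng)

    if config.size_dependent_signal:
        # carry probability grows with size rank: smallest ~0.1, largest ~1.0
        rank = rankdata(sizes)
        carry_p = config.signal_strength * (0.1 + 0.9 * (rank - 1) / max(len(rank) - 1, 1))
    else:
        carry_p = np.full(config.n_pathways_l3, config.signal_strength)

    # pathways partition the metabolite pool: a seeded shuffle sliced into
    # consecutive blocks of the drawn sizes
    assignment = rng.permutation(config.n_metabolites)
    members: dict[str, list[str]] = {}
    carries: dict[str, list[str]] = {}
    motifs_by_met: dict[str, list[int]] = {m: [] for m in met_ids}
    cursor = 0
    for k, pid in enumerate(l3_ids):
        chosen = sorted(assignment[cursor : cursor + sizes[k]])
        cursor += sizes[k]
        members[pid] = [met_ids[i] for i in chosen]
        carrying = [m for m in members[pid] if rng.random() < carry_p[k]]
        carries[pid] = carrying
        for m in carrying:
            motifs_by_met[m].append(k)

    l2_children: dict[str, list[str]] = {f"P2_{g:02d}": [] for g in range(config.n_pathways_l2)}
    for k, pid in enumerate(l3_ids):
        l2_children[f"P2_{k % config.n_pathways_l2:02d}"].append(pid)

    rows = []
    for pid in l3_ids:
        rows.extend((pid, "L3", m) for m in members[pid])
    for l2_id in sorted(l2_children):
        inherited = sorted({m for child in l2_children[l2_id] for m in members[child]})
        rows.extend((l2_id, "L2", m) for m in inherited)
    membership = pd.DataFrame(rows, columns=["pathway_id", "level", "metabolite_id"])
    membership.to_csv(out_dir / "membership.tsv", sep="\t", index=False)

    # each pathway's characteristic chemistry: a distinct ordered pair of
    # over-sampled elements (primary boosted by element_tilt, secondary by
    # half of it), cycling through all ordered pairs
    elements = [e for e, _ in config.elements]
    pairs = list(itertools.permutations(elements, 2))
    tilt_by_pathway = {
        k: [(pairs[k % len(pairs)][0], config.element_tilt),
            (pairs[k % len(pairs)][1], max(config.element_tilt / 2, 1.0))]
        for k in range(config.n_pathways_l3)
    }
    for mid in met_ids:
        carried = motifs_by_met[mid]
        _, text = generate_molecule(
            config,
            mid,
            [motifs[k] for k in carried],
            rng,
            tilt_elements=[t for k in carried for t in tilt_by_pathway[k]],
        )
        (mol_dir / f"{mid}.mol").write_text(text)

    manifest = {
        "config": asdict(config),
        "motifs": {
            pid: {"elements": list(motifs[k].elements), "bond_orders": list(motifs[k].bond_orders)}
            for k, pid in enumerate(l3_ids)
        },
        "l3_sizes": {pid: int(sizes[k]) for k, pid in enumerate(l3_ids)},
        "l2_children": {k: v for k, v in sorted(l2_children.items())},
        "members": members,
        "motif_carriers": carries,
        "carry_probability": {pid: float(carry_p[k]) for k, pid in enumerate(l3_ids)},
        "tilt_elements": {
            pid: [[el, float(m)] for el, m in tilt_by_pathway[k]]
            for k, pid in enumerate(l3_ids)
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
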
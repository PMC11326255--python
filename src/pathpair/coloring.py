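"""Atom-coloring substructure count features for molecular graphs.

Each atom is assigned a *color* at every radius r: at r=0 the color is the
element symbol; at r>0 it is the element followed by the lexicographically
sorted list of ``bond_order:neighbor-color-at-radius-(r-1)`` terms, wrapped
in parentheses.  Sorting the sub-colors makes the identifier canonical —
invariant under any re-ordering of atom indices — without resorting to
graph-isomorphism machinery.

An atom keeps emitting colors at increasing radii while its bond-distance
neighborhood (the ball of radius r around it) is still growing; once the
ball covers everything it will ever reach (bounded by the graph diameter,
or by the atom's connected component in multi-fragment molecules) the atom
stops emitting, so feature totals stay finite and graph-size bounded.  A
molecule's feature vector is the multiset of all emitted colors.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

from .molgraph import MolecularGraph


@dataclass(frozen=True)
class CountVector:
    """Sparse color -> value map for one metabolite (or one pathway).

    ``counts`` holds positive integers straight out of :func:`color_atoms`
    and positive reals after entry-wise normalization; ``bond_count`` is
    carried along because the softmax normalization divides by it.
    """

    metabolite_id: str
    counts: Mapping[str, float]
    bond_count: int

    def __post_init__(self) -> None:
        if self.bond_count < 0:
            raise ValueError(f"{self.metabolite_id}: negative bond count")
        if any(v <= 0 for v in self.counts.values()):
            raise ValueError(f"{self.metabolite_id}: non-positive count present")


def color_atoms(graph: MolecularGraph) -> CountVector:
    """Compute the full multi-radius atom-color count vector of a graph.

    The sum of radius-0 color counts always equals the non-hydrogen atom
    count, since every atom emits exactly one radius-0 color.
    """
    n = graph.atom_count
    adjacency: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for a, b, order in graph.bonds:
        adjacency[a].append((b, order))
        adjacency[b].append((a, order))

    counts: Counter[str] = Counter()
    colors = list(graph.atoms)
    counts.update(colors)

    balls = [frozenset({i}) for i in range(n)]
    active = set(range(n))
    while active:
        new_colors = [
            f"{graph.atoms[i]}(" + ",".join(sorted(f"{order}:{colors[j]}" for j, order in adjacency[i])) + ")"
            for i in range(n)
        ]
        new_balls = []
        still_active = set()
        for i in range(n):
            if i in active:
                grown = frozenset().union(balls[i], *(balls[j] for j, _ in adjacency[i]))
            else:
                grown = balls[i]
            new_balls.append(grown)
            if len(grown) > len(balls[i]):
                still_active.add(i)
                counts[new_colors[i]] += 1
        colors = new_colors
        balls = new_balls
        active = still_active

    return CountVector(
        metabolite_id=graph.metabolite_id,
        counts=dict(counts),
        bond_count=graph.bond_count,
    )


def build_vocabulary(corpus: Iterable[CountVector]) -> dict[str, int]:
    """Map every color occurring in the corpus to a column index.

    Ordering is lexicographic by identifier, so the vocabulary is
    deterministic and only grows when new colors appear.  No
    minimum-frequency pruning is applied.
    """
    colors: set[str] = set()
    n_vectors = 0
    for vec in corpus:
        colors.update(vec.counts)
        n_vectors += 1
    if n_vectors == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    return {color: idx for idx, color in enumerate(sorted(colors))}


def vectors_to_matrix(
    vectors: Sequence[CountVector],
    vocabulary: Mapping[str, int],
    dtype=np.float64,
) -> sparse.csr_matrix:
    """Stack count vectors into a CSR matrix under a fixed vocabulary.

    Colors absent from the vocabulary raise: the vocabulary is a column
    contract, not a filter.
    """
    data: list[float] = []
    indices: list[int] = []
    indptr = [0]
    for vec in vectors:
        cols = []
        for color, value in vec.counts.items():
            if color not in vocabulary:
                raise KeyError(f"{vec.metabolite_id}: color {color!r} not in vocabulary")
            cols.append((vocabulary[color], value))
        cols.sort()
        indices.extend(c for c, _ in cols)
        data.extend(v for _, v in cols)
        indptr.append(len(indices))
    return sparse.csr_matrix(
        (np.asarray(data, dtype=dtype), np.asarray(indices, dtype=np.int64), np.asarray(indptr, dtype=np.int64)),
        shape=(len(vectors), len(vocabulary)),
    )
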
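"""Dataset engineering: pathway features, normalizations, and the cross join.

The pipeline order is fixed: entry-wise softmax normalization of metabolite
and pathway count vectors, then the metabolite x pathway cross join, then
(per evaluation split) feature-wise min/max scaling fit on the training
entries only.  Metabolite and pathway feature columns live in disjoint
namespaces (``met::`` / ``pw::``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import sparse

from .coloring import CountVector, build_vocabulary, color_atoms, vectors_to_matrix
from .molgraph import MolecularGraph

logger = logging.getLogger(__name__)

LEVELS = ("L2", "L3")
MET_PREFIX = "met::"
PW_PREFIX = "pw::"


@dataclass(frozen=True)
class PathwayDefinition:
    """A pathway (or pathway category) as a set of member metabolites.

    Size is measured two ways: the number of member metabolites
    (``size_compounds``) and the total non-hydrogen atom count summed over
    members (``size_atoms``).
    """

    pathway_id: str
    level: str
    member_ids: frozenset[str]
    size_compounds: int
    size_atoms: int

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"{self.pathway_id}: level must be one of {LEVELS}")
        if self.size_compounds < 1 or self.size_compounds != len(self.member_ids):
            raise ValueError(f"{self.pathway_id}: inconsistent compound size")
        if self.size_atoms < self.size_compounds:
            raise ValueError(f"{self.pathway_id}: atom size below compound size")

    def size(self, metric: str) -> int:
        if metric == "compounds":
            return self.size_compounds
        if metric == "atoms":
            return self.size_atoms
        raise ValueError(f"unknown size metric {metric!r}")


def read_membership(path: str | Path) -> pd.DataFrame:
    """Read a pathway membership TSV (pathway_id, level, metabolite_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"pathway_id", "level", "metabolite_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"membership table must have columns {sorted(required)}")
    bad = set(df["level"]) - set(LEVELS)
    if bad:
        raise ValueError(f"unknown hierarchy levels in membership table: {sorted(bad)}")
    conflicting = df.groupby("pathway_id")["level"].nunique()
    conflicting = conflicting[conflicting > 1]
    if len(conflicting):
        raise ValueError(f"pathways listed under multiple levels: {list(conflicting.index)}")
    return df.drop_duplicates(ignore_index=True)


def build_pathway_definitions(
    membership: pd.DataFrame,
    graphs: Mapping[str, MolecularGraph],
    drop_missing: bool = False,
) -> list[PathwayDefinition]:
    """Turn a membership table into sized :class:`PathwayDefinition` objects.

    Members without a parsed structure either abort (default) or are dropped
    with a warning when ``drop_missing`` is set.
    """
    defs = []
    for pid, grp in membership.groupby("pathway_id", sort=True):
        members = set(grp["metabolite_id"])
        missing = members - set(graphs)
        if missing:
            if not drop_missing:
                raise KeyError(
                    f"pathway {pid}: members without structures: {sorted(missing)[:5]}"
                    + ("..." if len(missing) > 5 else "")
                )
            logger.warning("pathway %s: dropping %d members without structures", pid, len(missing))
            members -= missing
        if not members:
            raise ValueError(f"pathway {pid}: no members with structures")
        defs.append(
            PathwayDefinition(
                pathway_id=str(pid),
                level=str(grp["level"].iloc[0]),
                member_ids=frozenset(members),
                size_compounds=len(members),
                size_atoms=sum(graphs[m].atom_count for m in members),
            )
        )
    return defs


def build_pathway_features(
    pathways: Sequence[PathwayDefinition],
    metabolite_vectors: Mapping[str, CountVector],
) -> dict[str, CountVector]:
    """Aggregate member count vectors into one raw count vector per pathway.

    The pathway's chemical-structure representation is the element-wise sum
    of its members' color counts; its bond count is the members' total.
    """
    out: dict[str, CountVector] = {}
    for pw in pathways:
        counts: dict[str, float] = {}
        bond_count = 0
        for mid in sorted(pw.member_ids):
            vec = metabolite_vectors.get(mid)
            if vec is None:
                raise KeyError(f"pathway {pw.pathway_id}: member {mid} has no feature vector")
            for color, value in vec.counts.items():
                counts[color] = counts.get(color, 0) + value
            bond_count += vec.bond_count
        out[pw.pathway_id] = CountVector(
            metabolite_id=pw.pathway_id, counts=counts, bond_count=bond_count
        )
    return out


def softmax_by_bond_count(vec: CountVector) -> CountVector:
    """Entry-wise softmax over the non-zero colors, with counts divided by
    the entry's bond count before exponentiation.

    ``out_i = exp(c_i / B) / sum_j exp(c_j / B)`` over the non-zero colors
    only (a dense softmax over the full vocabulary would flatten every
    vector toward uniform); zero counts stay zero, and the non-zero outputs
    sum to one.  Bond-less single-atom entries use B = 1.
    """
    if not vec.counts:
        raise ValueError(f"{vec.metabolite_id}: cannot normalize an all-zero vector")
    b = max(vec.bond_count, 1)
    colors = sorted(vec.counts)
    z = np.array([vec.counts[c] for c in colors], dtype=np.float64) / b
    z -= z.max()  # numerical stability; softmax is shift-invariant
    e = np.exp(z)
    probs = e / e.sum()
    return CountVector(
        metabolite_id=vec.metabolite_id,
        counts={c: float(p) for c, p in zip(colors, probs)},
        bond_count=vec.bond_count,
    )


@dataclass
class PairedDataset:
    """Cross-joined metabolite-pathway entries with a shared column contract.

    Row order is metabolite-major: entry ``m * n_pathways + p`` pairs the
    m-th metabolite with the p-th pathway (both in sorted-id order at build
    time).  ``X`` is CSR; ``feature_names`` concatenates the ``met::`` and
    ``pw::`` namespaces.
    """

    X: sparse.csr_matrix
    y: np.ndarray
    metabolite_ids: np.ndarray
    pathway_ids: np.ndarray
    levels: np.ndarray
    feature_names: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if not (len(self.y) == len(self.metabolite_ids) == len(self.pathway_ids) == len(self.levels) == n):
            raise ValueError("entry-aligned arrays disagree on length")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature matrix width disagrees with feature names")

    @property
    def n_entries(self) -> int:
        return self.X.shape[0]

    @property
    def n_metabolite_features(self) -> int:
        return sum(1 for n in self.feature_names if n.startswith(MET_PREFIX))

    @property
    def n_pathway_features(self) -> int:
        return sum(1 for n in self.feature_names if n.startswith(PW_PREFIX))

    def subset(self, rows: np.ndarray) -> "PairedDataset":
        return PairedDataset(
            X=self.X[rows],
            y=self.y[rows],
            metabolite_ids=self.metabolite_ids[rows],
            pathway_ids=self.pathway_ids[rows],
            levels=self.levels[rows],
            feature_names=self.feature_names,
            provenance=dict(self.provenance),
        )

    # -- HDF5 persistence ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the dataset to a single HDF5 file (sparse CSR layout).

        ``track_times=False`` keeps rebuilt files byte-identical for
        identical inputs.
        """
        opts = dict(track_times=False)
        with h5py.File(path, "w", track_order=True) as f:
            feats = f.create_group("features")
            feats.create_dataset("data", data=self.X.data, **opts)
            feats.create_dataset("indices", data=self.X.indices.astype(np.int64), **opts)
            feats.create_dataset("indptr", data=self.X.indptr.astype(np.int64), **opts)
            feats.create_dataset("shape", data=np.asarray(self.X.shape, dtype=np.int64), **opts)
            str_dt = h5py.string_dtype("utf-8")
            feats.create_dataset("names", data=np.asarray(self.feature_names, dtype=object), dtype=str_dt, **opts)
            f.create_dataset("labels", data=self.y.astype(np.int8), **opts)
            f.create_dataset("metabolite_ids", data=self.metabolite_ids.astype(object), dtype=str_dt, **opts)
            f.create_dataset("pathway_ids", data=self.pathway_ids.astype(object), dtype=str_dt, **opts)
            f.create_dataset("levels", data=self.levels.astype(object), dtype=str_dt, **opts)
            f.create_dataset(
                "provenance",
                data=json.dumps(self.provenance, sort_keys=True),
                dtype=str_dt,
                **opts,
            )

    @classmethod
    def load(cls, path: str | Path) -> "PairedDataset":
        with h5py.File(path, "r") as f:
            feats = f["features"]
            shape = tuple(feats["shape"][:])
            X = sparse.csr_matrix(
                (feats["data"][:], feats["indices"][:], feats["indptr"][:]), shape=shape
            )
            decode = np.vectorize(lambda b: b.decode() if isinstance(b, bytes) else str(b))
            return cls(
                X=X,
                y=f["labels"][:].astype(np.int8),
                metabolite_ids=decode(f["metabolite_ids"][:]),
                pathway_ids=decode(f["pathway_ids"][:]),
                levels=decode(f["levels"][:]),
                feature_names=tuple(decode(feats["names"][:])),
                provenance=json.loads(f["provenance"][()]),
            )


def cross_join(
    metabolite_vectors: Mapping[str, CountVector],
    pathway_vectors: Mapping[str, CountVector],
    membership: pd.DataFrame,
    pair_overrides: Mapping[tuple[str, str], CountVector] | None = None,
) -> PairedDataset:
    """Pair every metabolite with every pathway into one labeled dataset.

    Produces exactly ``|M| x |P|`` entries; the label is 1 iff the
    membership table lists the metabolite under the pathway.  Metabolite
    and pathway vocabularies are built independently (pathway colors are a
    subset of the union of their members' colors) and concatenated under
    the ``met::`` / ``pw::`` namespaces.

    ``pair_overrides`` substitutes the pathway-side vector of specific
    (metabolite_id, pathway_id) pairs; :func:`build_dataset` uses this for
    leave-one-out pathway features on positive pairs.  Override colors must
    be a subset of the pathway vocabulary.
    """
    if not metabolite_vectors or not pathway_vectors:
        raise ValueError("cross join requires non-empty metabolite and pathway sets")
    met_ids = sorted(metabolite_vectors)
    pw_ids = sorted(pathway_vectors)
    if len(set(met_ids)) != len(met_ids) or len(set(pw_ids)) != len(pw_ids):
        raise ValueError("duplicated metabolite or pathway ids")

    met_vocab = build_vocabulary(metabolite_vectors[m] for m in met_ids)
    pw_vocab = build_vocabulary(pathway_vectors[p] for p in pw_ids)
    met_X = vectors_to_matrix([metabolite_vectors[m] for m in met_ids], met_vocab)
    pw_X = vectors_to_matrix([pathway_vectors[p] for p in pw_ids], pw_vocab)

    n_m, n_p = len(met_ids), len(pw_ids)
    row_met = np.repeat(np.arange(n_m), n_p)
    row_pw = np.tile(np.arange(n_p), n_m)

    row_pw_feat = row_pw
    if pair_overrides:
        met_pos = {m: i for i, m in enumerate(met_ids)}
        pw_pos = {p: j for j, p in enumerate(pw_ids)}
        override_vecs = []
        row_pw_feat = row_pw.copy()
        for k, ((m, p), vec) in enumerate(sorted(pair_overrides.items())):
            if m not in met_pos or p not in pw_pos:
                raise KeyError(f"override for unknown pair ({m}, {p})")
            row_pw_feat[met_pos[m] * n_p + pw_pos[p]] = n_p + k
            override_vecs.append(vec)
        pw_X = sparse.vstack(
            [pw_X, vectors_to_matrix(override_vecs, pw_vocab)], format="csr"
        )

    X = sparse.hstack([met_X[row_met], pw_X[row_pw_feat]], format="csr")

    member_pairs = set(zip(membership["metabolite_id"], membership["pathway_id"]))
    levels_by_pw = dict(zip(membership["pathway_id"], membership["level"]))
    met_arr = np.asarray(met_ids, dtype=object)[row_met]
    pw_arr = np.asarray(pw_ids, dtype=object)[row_pw]
    y = np.fromiter(
        ((m, p) in member_pairs for m, p in zip(met_arr, pw_arr)),
        dtype=np.int8,
        count=n_m * n_p,
    )
    level_arr = np.asarray([levels_by_pw.get(p, "L3") for p in pw_arr], dtype=object)

    names = tuple(
        [MET_PREFIX + c for c in sorted(met_vocab, key=met_vocab.get)]
        + [PW_PREFIX + c for c in sorted(pw_vocab, key=pw_vocab.get)]
    )
    return PairedDataset(
        X=X,
        y=y,
        metabolite_ids=met_arr,
        pathway_ids=pw_arr,
        levels=level_arr,
        feature_names=names,
        provenance={"n_metabolites": n_m, "n_pathways": n_p},
    )


def minmax_scale(
    X: sparse.csr_matrix, fit_rows: np.ndarray
) -> tuple[sparse.csr_matrix, tuple[np.ndarray, np.ndarray]]:
    """Feature-wise min/max scaling fit on ``fit_rows``, applied to all rows.

    Each fit column maps onto [0, 1]; constant columns map to 0; values
    outside the fit range (in non-fit rows) are clipped to [0, 1].
    Implicit zeros are preserved wherever the column minimum is zero, which
    for non-negative sparse features is almost every column.
    """
    if len(fit_rows) == 0:
        raise ValueError("min/max scaling requires a non-empty fit subset")
    fit = X[fit_rows]
    col_max = np.asarray(fit.max(axis=0).todense()).ravel()
    col_min = np.asarray(fit.min(axis=0).todense()).ravel()
    denom = col_max - col_min
    scale = np.divide(1.0, denom, out=np.zeros_like(denom), where=denom != 0)

    offset = col_min * scale
    offset_cols = np.nonzero(offset)[0]
    if offset_cols.size:
        # Columns with a non-zero fit minimum: shift explicit entries by the
        # offset in CSC storage.  Implicit zeros in such columns sit below
        # the fit minimum and are clipped to 0 anyway, so sparsity is safe.
        Xs = X.multiply(scale).tocsc()
        for c in offset_cols:
            lo, hi = Xs.indptr[c], Xs.indptr[c + 1]
            Xs.data[lo:hi] -= offset[c]
        Xs = Xs.tocsr()
    else:
        Xs = X.multiply(scale).tocsr()
    np.clip(Xs.data, 0.0, 1.0, out=Xs.data)
    Xs.eliminate_zeros()
    return Xs, (col_min, col_max)


def filter_pathway_definitions(
    pathways: Sequence[PathwayDefinition], threshold: int, metric: str = "compounds"
) -> list[PathwayDefinition]:
    """Retain pathways whose size under ``metric`` is >= ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    kept = [p for p in pathways if p.size(metric) >= threshold]
    if not kept:
        raise ValueError(f"size threshold {threshold} ({metric}) removes every pathway")
    return kept


def filter_pathways_by_size(
    dataset: PairedDataset,
    pathways: Sequence[PathwayDefinition],
    threshold: int,
    metric: str = "compounds",
) -> PairedDataset:
    """Drop all cross-join entries (both labels) of pathways below a size threshold."""
    kept = {p.pathway_id for p in filter_pathway_definitions(pathways, threshold, metric)}
    mask = np.fromiter((p in kept for p in dataset.pathway_ids), dtype=bool, count=dataset.n_entries)
    out = dataset.subset(np.nonzero(mask)[0])
    out.provenance = dict(out.provenance)
    out.provenance.setdefault("size_filters", []).append(
        {"threshold": int(threshold), "metric": metric, "n_retained": len(kept)}
    )
    out.provenance["n_pathways"] = len(kept)
    return out


def build_dataset(
    graphs: Mapping[str, MolecularGraph],
    membership: pd.DataFrame,
    levels: Sequence[str] = LEVELS,
    drop_missing: bool = False,
    exclude_query_metabolite: bool = False,
) -> tuple[PairedDataset, list[PathwayDefinition]]:
    """End-to-end feature build: color, aggregate, normalize, cross join.

    Restricting ``levels`` builds the L2-only or L3-only variants; both
    levels together give the combined dataset.

    By default a pathway's feature vector sums over *all* its members,
    including the query metabolite of a positive pair.  This keeps the
    pathway representation pair-independent, but it means membership is
    partially encoded in the features: a classifier can notice that a
    metabolite's own (often distinctive) colors are contained in the
    pathway vector, which inflates held-out scores.  Setting
    ``exclude_query_metabolite=True`` subtracts the query metabolite's
    counts from the pathway sum of its positive pairs before
    normalization (leave-one-out); note the per-pair perturbation this
    introduces is itself label-correlated, so neither variant is free of
    the bias.  A pathway whose only member is the query metabolite gets
    an all-zero pathway block for that pair under leave-one-out.
    """
    membership = membership[membership["level"].isin(levels)].reset_index(drop=True)
    if membership.empty:
        raise ValueError(f"membership table has no rows at levels {list(levels)}")
    missing = set(membership["metabolite_id"]) - set(graphs)
    if missing and not drop_missing:
        raise KeyError(
            f"membership references metabolites without molfiles: {sorted(missing)[:5]}"
            + ("..." if len(missing) > 5 else "")
        )

    defs = build_pathway_definitions(membership, graphs, drop_missing=drop_missing)
    met_vectors = {mid: color_atoms(g) for mid, g in graphs.items()}
    pw_raw = build_pathway_features(defs, met_vectors)
    met_norm = {m: softmax_by_bond_count(v) for m, v in met_vectors.items()}
    pw_norm = {p: softmax_by_bond_count(v) for p, v in pw_raw.items()}
    overrides: dict[tuple[str, str], CountVector] = {}
    if exclude_query_metabolite:
        for pw in defs:
            full = pw_raw[pw.pathway_id]
            for mid in pw.member_ids:
                member = met_vectors[mid]
                loo = {
                    c: v - member.counts.get(c, 0)
                    for c, v in full.counts.items()
                    if v - member.counts.get(c, 0) > 0
                }
                vec = CountVector(
                    metabolite_id=pw.pathway_id,
                    counts=loo,
                    bond_count=max(full.bond_count - member.bond_count, 0),
                )
                overrides[(mid, pw.pathway_id)] = (
                    softmax_by_bond_count(vec) if loo else vec
                )
    ds = cross_join(met_norm, pw_norm, membership, pair_overrides=overrides or None)
    ds.provenance.update(
        {
            "levels": sorted(set(membership["level"])),
            "metabolite_atom_counts": {m: g.atom_count for m, g in sorted(graphs.items())},
            "pathway_sizes": {
                d.pathway_id: {
                    "level": d.level,
                    "size_compounds": d.size_compounds,
                    "size_atoms": d.size_atoms,
                }
                for d in defs
            },
        }
    )
    return ds, defs


def pathway_definitions_from_dataset(dataset: PairedDataset) -> list[PathwayDefinition]:
    """Reconstruct sized pathway definitions from a dataset's labels + provenance."""
    sizes = dataset.provenance.get("pathway_sizes")
    if sizes is None:
        raise ValueError("dataset provenance lacks pathway size records")
    members: dict[str, set[str]] = {}
    pos = dataset.y == 1
    for m, p in zip(dataset.metabolite_ids[pos], dataset.pathway_ids[pos]):
        members.setdefault(p, set()).add(m)
    return [
        PathwayDefinition(
            pathway_id=pid,
            level=rec["level"],
            member_ids=frozenset(members.get(pid, set())),
            size_compounds=rec["size_compounds"],
            size_atoms=rec["size_atoms"],
        )
        for pid, rec in sorted(sizes.items())
    ]
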
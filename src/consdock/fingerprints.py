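"""Consensus protein-ligand interaction fingerprints.

A ligand's contacts from two independent docking placement algorithms are
intersected on the key (interaction_type, residue_number, residue_type,
chain): only contacts reproduced by both programs enter the consensus set.
The union of all consensus keys defines a named bit universe
("type@resnum@restype@chain"); ligands become binary presence/absence
vectors, compared by Tanimoto similarity and grouped by agglomerative
clustering on 1 - T.  An empty consensus set (no reproducible contact)
is itself informative — such a ligand is unlikely to bind at the site —
so empty fingerprints are kept as all-zero rows and, by convention, have
Tanimoto 0 to everything including each other.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import InteractionRecord

__all__ = [
    "ConsensusInteractionSet",
    "FingerprintMatrix",
    "SimilarityMatrix",
    "Dendrogram",
    "merge_consensus_interactions",
    "build_fingerprint_matrix",
    "tanimoto_matrix",
    "cluster_fingerprints",
]

Key = tuple[str, int, str, str]
Linkage = Literal["average", "complete", "single"]


@dataclass
class ConsensusInteractionSet:
    ligand_id: str
    interactions: frozenset[Key]

    def __len__(self) -> int:
        return len(self.interactions)


@dataclass
class FingerprintMatrix:
    """Binary ligand x interaction-bit matrix with stable, named bits.

    Bits are ordered lexicographically by (chain, residue_number,
    residue_type, interaction_type) so serialization is deterministic.
    """

    bit_names: list[str]
    matrix: pd.DataFrame  # ligand x bit, values 0/1

    @property
    def ligand_ids(self) -> list[str]:
        return list(self.matrix.index)


@dataclass
class SimilarityMatrix:
    ligand_ids: list[str]
    values: np.ndarray
    empty_ligands: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ligand_ids, columns=self.ligand_ids)


@dataclass
class Dendrogram:
    """Agglomerative merge tree: each merge is (left, right, height, size)
    where left/right index either leaves (0..n-1) or earlier merges (n+k)."""

    merges: list[tuple[int, int, float, int]]
    leaf_order: list[int]
    ligand_ids: list[str]

    def ordered_ligands(self) -> list[str]:
        return [self.ligand_ids[i] for i in self.leaf_order]

    def to_json(self) -> str:
        return json.dumps(
            {
                "ligand_ids": self.ligand_ids,
                "merges": [list(m) for m in self.merges],
                "leaf_order": self.leaf_order,
            },
            indent=2,
        )


def _key_name(key: Key) -> str:
    itype, resnr, restype, chain = key
    return f"{itype}@{resnr}@{restype}@{chain}"


def merge_consensus_interactions(
    records_a: Sequence[InteractionRecord],
    records_b: Sequence[InteractionRecord],
) -> list[ConsensusInteractionSet]:
    """Intersect the interaction key sets of two docking programs per
    ligand.

    Records in each argument must come from a single program, and the two
    programs must differ — a consensus over one placement algorithm would
    merely deduplicate its own contacts.  Ligands present in only one
    input get an empty consensus set (with a warning), like ligands whose
    two binding modes share no contact.
    """
    progs_a = {r.program for r in records_a}
    progs_b = {r.program for r in records_b}
    if len(progs_a) > 1 or len(progs_b) > 1:
        raise ValueError(
            f"each record list must come from one program, got {progs_a} / {progs_b}"
        )
    if progs_a and progs_b and progs_a == progs_b:
        raise ValueError(
            f"consensus requires two distinct programs, both inputs are {progs_a}"
        )

    keys_a: dict[str, set[Key]] = {}
    keys_b: dict[str, set[Key]] = {}
    for recs, store in ((records_a, keys_a), (records_b, keys_b)):
        for r in recs:
            store.setdefault(r.ligand_id, set()).add(r.key)

    all_ligands = sorted(set(keys_a) | set(keys_b))
    one_sided = sorted((set(keys_a) ^ set(keys_b)))
    if one_sided:
        warnings.warn(
            f"ligand(s) present in only one program get empty consensus: {one_sided}",
            stacklevel=2,
        )
    return [
        ConsensusInteractionSet(
            ligand_id=lig,
            interactions=frozenset(keys_a.get(lig, set()) & keys_b.get(lig, set())),
        )
        for lig in all_ligands
    ]


def build_fingerprint_matrix(
    sets: Sequence[ConsensusInteractionSet],
) -> FingerprintMatrix:
    """Encode consensus sets as a binary matrix over the union of keys.

    Ligands with empty consensus sets keep an all-zero row; the bit
    universe is the union of consensus keys only (contacts seen by a
    single program never become bits).
    """
    if not sets:
        raise ValueError("need at least one ligand")
    universe = sorted(
        {k for s in sets for k in s.interactions},
        key=lambda k: (k[3], k[1], k[2], k[0]),  # chain, resnr, restype, type
    )
    names = [_key_name(k) for k in universe]
    rows = {
        s.ligand_id: [1 if k in s.interactions else 0 for k in universe]
        for s in sets
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=names, dtype=int)
    df = df.loc[[s.ligand_id for s in sets]]
    df.index.name = "ligand_id"
    return FingerprintMatrix(bit_names=names, matrix=df)


def tanimoto_matrix(fp: FingerprintMatrix) -> SimilarityMatrix:
    """Pairwise Tanimoto similarity T = |A&B| / |A|B| on the bit sets.

    T = 0 by convention when the union is empty, so two empty fingerprints
    are maximally dissimilar rather than identical; affected ligands are
    flagged in ``empty_ligands``.
    """
    m = fp.matrix.to_numpy(dtype=float)
    inter = m @ m.T
    sizes = m.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    empty = sizes == 0
    t[empty, :] = 0.0
    t[:, empty] = 0.0
    np.fill_diagonal(t, np.where(empty, 0.0, 1.0))
    return SimilarityMatrix(
        ligand_ids=fp.ligand_ids,
        values=t,
        empty_ligands=[l for l, e in zip(fp.ligand_ids, empty) if e],
    )


def cluster_fingerprints(
    sim: SimilarityMatrix, linkage: Linkage = "average"
) -> Dendrogram:
    """Agglomerative clustering on distance d = 1 - T.

    Merges the closest pair of clusters at each step; ties are broken
    deterministically by the smallest (i, j) pair in input ligand order,
    so identical inputs always give identical trees.  Heights are the
    linkage distances (average, complete or single).
    """
    n = len(sim.ligand_ids)
    if n < 2:
        raise ValueError("need at least 2 ligands to cluster")
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unknown linkage {linkage!r}")
    d = 1.0 - sim.values
    np.fill_diagonal(d, 0.0)

    # active cluster id -> member leaf indices; ids 0..n-1 are leaves,
    # merge k creates id n+k
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    active: list[int] = list(range(n))
    merges: list[tuple[int, int, float, int]] = []
    children: dict[int, tuple[int, int]] = {}

    def cluster_dist(a: int, b: int) -> float:
        block = d[np.ix_(members[a], members[b])]
        if linkage == "average":
            return float(block.mean())
        if linkage == "complete":
            return float(block.max())
        return float(block.min())

    while len(active) > 1:
        best: tuple[float, int, int] | None = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                dist = cluster_dist(active[i], active[j])
                cand = (dist, i, j)
                if best is None or cand < best:
                    best = cand
        dist, i, j = best  # type: ignore[misc]
        a, b = active[i], active[j]
        new_id = n + len(merges)
        members[new_id] = members[a] + members[b]
        children[new_id] = (a, b)
        merges.append((a, b, dist, len(members[new_id])))
        active = [c for c in active if c not in (a, b)] + [new_id]

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        l, r = children[node]
        return leaves(l) + leaves(r)

    return Dendrogram(
        merges=merges, leaf_order=leaves(active[0]), ligand_ids=list(sim.ligand_ids)
    )
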
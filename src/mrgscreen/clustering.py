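"""Structure-activity clustering of hit compounds.

Hits are fingerprinted with extended-connectivity circular substructures
(ECFP4: Morgan radius 2, folded to 2048 bits) and compared by Tanimoto
similarity (intersection over union of the bitsets).  Clusters are formed by
greedy sphere exclusion at a similarity cutoff (Butina's algorithm): the
unassigned compound with the most unassigned neighbors at similarity >=
cutoff becomes a centroid and absorbs those neighbors; ties are broken by
lexicographic compound id, which makes the partition independent of input
order.  Clusters below a minimum reportable size are kept in the full output
but listed as unclustered in the summary view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "Fingerprint",
    "Cluster",
    "ClusterSet",
    "fingerprint",
    "tanimoto",
    "similarity_matrix",
    "cluster_from_similarity",
    "cluster",
]


@dataclass(frozen=True)
class Fingerprint:
    """Folded circular-substructure fingerprint of one compound."""

    compound_id: str
    bits: np.ndarray  # boolean, length n_bits
    radius: int = 2
    n_bits: int = 2048

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


def fingerprint(
    smiles: str,
    compound_id: str = "",
    *,
    radius: int = 2,
    n_bits: int = 2048,
) -> Fingerprint:
    """ECFP-style fingerprint from a SMILES string.

    The SMILES is canonicalized on parsing, so different writings of the
    same molecule give identical bitsets.  An unparseable or empty SMILES
    raises a ValueError carrying the compound id.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError(f"unparseable SMILES for compound {compound_id!r}: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    bits = np.zeros(n_bits, dtype=bool)
    bits[list(bv.GetOnBits())] = True
    return Fingerprint(compound_id=compound_id, bits=bits, radius=radius, n_bits=n_bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two same-length bitsets.

    Two all-zero fingerprints compare as 1.0 (identical emptiness), with a
    warning since that usually signals an upstream problem.
    """
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    union = int(np.logical_or(a.bits, b.bits).sum())
    if union == 0:
        log.warning("tanimoto of two empty fingerprints (%r, %r)", a.compound_id, b.compound_id)
        return 1.0
    inter = int(np.logical_and(a.bits, b.bits).sum())
    return inter / union


def similarity_matrix(fingerprints: Sequence[Fingerprint]) -> np.ndarray:
    """Dense pairwise Tanimoto matrix (diagonal = 1)."""
    n = len(fingerprints)
    if n == 0:
        raise ValueError("no fingerprints")
    bits = np.stack([fp.bits for fp in fingerprints]).astype(np.int64)
    inter = bits @ bits.T
    pops = bits.sum(axis=1)
    union = pops[:, None] + pops[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(sim, 1.0)
    return sim


@dataclass(frozen=True)
class Cluster:
    centroid: str
    members: tuple[str, ...]  # includes the centroid
    mean_similarity: float  # centroid-to-member mean (NaN for singletons)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    """Sphere-exclusion clustering result.

    ``clusters`` is the full partition (every input id appears in exactly
    one cluster, singletons included).  The summary view reports clusters
    with at least ``min_report_size`` members; the remaining ids appear in
    ``unclustered``.
    """

    clusters: list[Cluster]
    similarity_cutoff: float = 0.6
    min_report_size: int = 3

    @property
    def major_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.size >= self.min_report_size]

    @property
    def unclustered(self) -> list[str]:
        out = []
        for c in self.clusters:
            if c.size < self.min_report_size:
                out.extend(c.members)
        return sorted(out)

    @property
    def all_ids(self) -> list[str]:
        out = []
        for c in self.clusters:
            out.extend(c.members)
        return sorted(out)

    def summary(self) -> dict:
        return {
            "similarity_cutoff": self.similarity_cutoff,
            "min_report_size": self.min_report_size,
            "n_clusters": len(self.major_clusters),
            "n_compounds_clustered": sum(c.size for c in self.major_clusters),
            "clusters": [
                {
                    "centroid": c.centroid,
                    "size": c.size,
                    "members": list(c.members),
                    "mean_similarity": c.mean_similarity,
                }
                for c in self.major_clusters
            ],
            "unclustered": self.unclustered,
        }


def cluster_from_similarity(
    ids: Sequence[str],
    similarity: np.ndarray,
    *,
    cutoff: float = 0.6,
    min_report_size: int = 3,
) -> ClusterSet:
    """Greedy sphere-exclusion clustering on a precomputed similarity matrix.

    Repeatedly picks the unassigned compound with the most unassigned
    neighbors (similarity >= cutoff, self excluded) as a centroid and
    assigns it together with those neighbors; ties on neighbor count break
    to the lexicographically smallest id.
    """
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound ids")
    sim = np.asarray(similarity, dtype=float)
    n = len(ids)
    if sim.shape != (n, n):
        raise ValueError(f"similarity matrix shape {sim.shape} != ({n}, {n})")
    neighbor = sim >= cutoff
    np.fill_diagonal(neighbor, False)

    unassigned = set(range(n))
    clusters: list[Cluster] = []
    while unassigned:
        best_i = min(
            unassigned,
            key=lambda i: (-sum(1 for j in np.nonzero(neighbor[i])[0] if j in unassigned), ids[i]),
        )
        members_idx = [best_i] + [
            j for j in np.nonzero(neighbor[best_i])[0] if j in unassigned and j != best_i
        ]
        unassigned -= set(members_idx)
        member_ids = sorted(ids[j] for j in members_idx)
        others = [j for j in members_idx if j != best_i]
        mean_sim = float(np.mean(sim[best_i, others])) if others else float("nan")
        clusters.append(
            Cluster(centroid=ids[best_i], members=tuple(member_ids), mean_similarity=mean_sim)
        )
    clusters.sort(key=lambda c: (-c.size, c.centroid))
    return ClusterSet(
        clusters=clusters,
        similarity_cutoff=cutoff,
        min_report_size=min_report_size,
    )


def cluster(
    fingerprints: Sequence[Fingerprint],
    *,
    cutoff: float = 0.6,
    min_report_size: int = 3,
) -> ClusterSet:
    """Butina-style clustering of fingerprints at a Tanimoto cutoff."""
    if not fingerprints:
        raise ValueError("no fingerprints to cluster")
    ids = [fp.compound_id for fp in fingerprints]
    sim = similarity_matrix(fingerprints)
    return cluster_from_similarity(ids, sim, cutoff=cutoff, min_report_size=min_report_size)
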
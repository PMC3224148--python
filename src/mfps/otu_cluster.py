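"""Pairwise distances and per-genus OTU clustering.

OTUs are complete-linkage clusters cut at a distance threshold (default
0.01, i.e. 99% similarity).  Complete linkage is the only linkage under
which "minimum within-cluster similarity of 99%" holds literally: every
pair inside an OTU is guaranteed to be within the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GAP, AlignmentSet, LEVELS, TaxonomyLabel
from .errors import LabelingError, UndefinedDistanceError


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over named sequences."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")

    def write_phylip_square(self, path) -> None:
        """Write the square (mothur/phylip "square" dialect) format."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, sid in enumerate(self.ids):
                row = "\t".join(f"{x:.6f}" for x in self.d[i])
                fh.write(f"{sid}\t{row}\n")


def pairwise_distances(aln: AlignmentSet) -> DistanceMatrix:
    """Fraction of mismatched columns among comparable columns, per pair.

    Gap policy: columns where both sequences are gapped are ignored;
    gap-versus-base counts as one mismatch per column.  A pair with zero
    comparable columns has no defined distance and raises.
    """
    if aln.n_sequences < 1:
        raise ValueError("empty alignment")
    m = aln.matrix
    is_gap = m == GAP
    n = aln.n_sequences
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        # vectorised over all later rows at once
        both_gap = is_gap[i][None, :] & is_gap[i + 1 :]
        comparable = (~both_gap).sum(axis=1)
        mism = ((m[i][None, :] != m[i + 1 :]) & ~both_gap).sum(axis=1)
        if np.any(comparable == 0):
            j = i + 1 + int(np.flatnonzero(comparable == 0)[0])
            raise UndefinedDistanceError(
                f"no comparable columns between {aln.ids[i]!r} and {aln.ids[j]!r}"
            )
        d[i, i + 1 :] = mism / comparable
    d = d + d.T
    return DistanceMatrix(ids=list(aln.ids), d=d)


def cluster_otus(dm: DistanceMatrix, threshold: float = 0.01) -> dict[str, str]:
    """Complete-linkage agglomerative clustering cut at ``threshold``.

    Merging proceeds while the smallest complete-linkage distance is at
    most the threshold; among equally close pairs the lexicographically
    smallest pair (by each cluster's smallest member index) is merged, so
    the result is deterministic.  OTU ids ("1", "2", ...) are assigned by
    order of each cluster's first member in the input.
    """
    n = len(dm.ids)
    if n == 0:
        return {}
    # each live cluster is keyed by its smallest member index; merges always
    # absorb into the smaller key, so keys give the lexicographic tie-break
    members: dict[int, list[int]] = {i: [i] for i in range(n)}

    def cluster_dist(a: int, b: int) -> float:
        return float(dm.d[np.ix_(members[a], members[b])].max())

    while len(members) > 1:
        keys = sorted(members)
        best = min(
            (cluster_dist(a, b), a, b)
            for i, a in enumerate(keys)
            for b in keys[i + 1 :]
        )
        if best[0] > threshold:
            break
        _, a, b = best
        members[a] = sorted(members[a] + members.pop(b))

    clusters = sorted(members.values(), key=min)
    out: dict[str, str] = {}
    for k, mem in enumerate(clusters, start=1):
        for i in mem:
            out[dm.ids[i]] = str(k)
    return out


def assign_otus_per_genus(
    aln: AlignmentSet,
    taxonomy: dict[str, TaxonomyLabel],
    threshold: float = 0.01,
) -> dict[str, str]:
    """Cluster each genus independently; OTU ids are genus-scoped."""
    missing = [sid for sid in aln.ids if sid not in taxonomy]
    if missing:
        raise LabelingError(missing)
    by_genus: dict[tuple[str, str], list[str]] = {}
    for sid in aln.ids:
        by_genus.setdefault(taxonomy[sid].key("genus"), []).append(sid)
    otus: dict[str, str] = {}
    for _, ids in sorted(by_genus.items()):
        sub = aln.subset_sequences(ids)
        dm = pairwise_distances(sub)
        otus.update(cluster_otus(dm, threshold))
    return otus


def label_set(
    aln: AlignmentSet,
    taxonomy: dict[str, TaxonomyLabel],
    otus: dict[str, str],
) -> AlignmentSet:
    """Attach full three-level labels (phylum, genus, genus-scoped OTU)."""
    missing = [sid for sid in aln.ids if sid not in taxonomy or sid not in otus]
    if missing:
        raise LabelingError(missing)
    out = aln.copy()
    out.taxonomy = {
        sid: TaxonomyLabel(
            phylum=taxonomy[sid].phylum, genus=taxonomy[sid].genus, otu=otus[sid]
        )
        for sid in aln.ids
    }
    return out


def write_otu_tsv(otus: dict[str, str], taxonomy: dict[str, TaxonomyLabel], path) -> None:
    with open(path, "w") as fh:
        for sid, otu in otus.items():
            fh.write(f"{sid}\t{taxonomy[sid].genus}\t{otu}\n")
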
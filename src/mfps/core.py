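"""Core containers: taxonomy labels and gapped multiple alignments.

Sequences are stored as a dense uint8 matrix of ASCII codes (rows =
sequences, columns = alignment columns), which makes column selection,
consensus calls and pairwise distance computation cheap numpy operations
while the public surface still speaks strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np

from .errors import FormatError

GAP_CHAR = "-"
GAP = ord(GAP_CHAR)
BASES = "ACGT"
BASE_CODES = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)

#: Taxonomic levels, finest first.  Group identity at a level is the full
#: lineage prefix down to that level, so groups nest by construction.
LEVELS = ("otu", "genus", "phylum")


@dataclass(frozen=True)
class TaxonomyLabel:
    """Three-level lineage of one sequence: phylum > genus > OTU.

    The OTU identifier is scoped within its genus; ``key`` returns the
    globally unique lineage tuple for a level so that groups at finer
    levels nest inside coarser ones.
    """

    phylum: str
    genus: str
    otu: str | None = None

    def key(self, level: str) -> tuple[str, ...]:
        if level == "phylum":
            return (self.phylum,)
        if level == "genus":
            return (self.phylum, self.genus)
        if level == "otu":
            if self.otu is None:
                raise ValueError(f"label has no OTU: {self}")
            return (self.phylum, self.genus, self.otu)
        raise ValueError(f"unknown taxonomic level: {level!r}")


def _to_matrix(seqs: Iterable[str]) -> np.ndarray:
    rows = [np.frombuffer(s.encode("ascii"), dtype=np.uint8) for s in seqs]
    if not rows:
        return np.zeros((0, 0), dtype=np.uint8)
    width = {r.size for r in rows}
    if len(width) != 1:
        raise FormatError(f"ragged alignment: sequence lengths {sorted(width)}")
    return np.vstack(rows)


@dataclass
class AlignmentSet:
    """An equal-width gapped alignment with optional column mask and taxonomy.

    ``mask`` is a boolean keep-flag per column (True = conserved / keep,
    False = hypervariable / drop).  ``col_origin`` tracks each current
    column's index in the original coordinate system across column
    selections, which lets callers reason about what a sequence of
    trimming operations retained.
    """

    ids: list[str]
    matrix: np.ndarray  # uint8, shape (n_sequences, n_columns)
    mask: np.ndarray | None = None
    taxonomy: dict[str, TaxonomyLabel] | None = None
    col_origin: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != self.matrix.shape[0]:
            raise FormatError("ids and matrix row count disagree")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise FormatError(f"duplicate sequence ids: {dupes}")
        if self.mask is not None and self.mask.size != self.n_columns:
            raise FormatError("mask length does not match column count")
        if self.col_origin is None:
            self.col_origin = np.arange(self.n_columns)

    # -- construction ---------------------------------------------------

    @classmethod
    def from_strings(
        cls,
        records: Iterable[tuple[str, str]],
        mask: np.ndarray | None = None,
        taxonomy: Mapping[str, TaxonomyLabel] | None = None,
    ) -> "AlignmentSet":
        ids, seqs = [], []
        for sid, seq in records:
            ids.append(sid)
            seqs.append(seq)
        return cls(
            ids=ids,
            matrix=_to_matrix(seqs),
            mask=None if mask is None else np.asarray(mask, dtype=bool),
            taxonomy=dict(taxonomy) if taxonomy is not None else None,
        )

    # -- basic accessors ------------------------------------------------

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def index_of(self, seq_id: str) -> int:
        try:
            return self.ids.index(seq_id)
        except ValueError:
            raise KeyError(seq_id) from None

    def sequence(self, seq_id: str) -> str:
        return self.matrix[self.index_of(seq_id)].tobytes().decode("ascii")

    def degapped(self, seq_id: str) -> str:
        row = self.matrix[self.index_of(seq_id)]
        return row[row != GAP].tobytes().decode("ascii")

    def iter_sequences(self) -> Iterator[tuple[str, str]]:
        for i, sid in enumerate(self.ids):
            yield sid, self.matrix[i].tobytes().decode("ascii")

    def degapped_all(self) -> dict[str, str]:
        return {sid: self.degapped(sid) for sid in self.ids}

    # -- consensus ------------------------------------------------------

    def consensus(self) -> np.ndarray:
        """Majority character per column (gap competes like a base).

        Ties are broken in the fixed order A < C < G < T < '-' so the
        result is deterministic.
        """
        order = np.frombuffer(b"ACGT-", dtype=np.uint8)
        out = np.empty(self.n_columns, dtype=np.uint8)
        # other codes (ambiguity letters) lose ties but can still win a column
        for j in range(self.n_columns):
            col = self.matrix[:, j]
            vals, counts = np.unique(col, return_counts=True)
            best = counts.max()
            winners = vals[counts == best]
            ranked = sorted(
                winners,
                key=lambda v: (list(order).index(v) if v in order else len(order), v),
            )
            out[j] = ranked[0]
        return out

    def consensus_string(self) -> str:
        return self.consensus().tobytes().decode("ascii")

    # -- subsetting -----------------------------------------------------

    def select_columns(self, keep) -> "AlignmentSet":
        """Return a copy restricted to the given columns.

        ``keep`` is a boolean mask or an integer index array in current
        coordinates; mask and col_origin are carried along.
        """
        keep = np.asarray(keep)
        if keep.dtype == bool:
            if keep.size != self.n_columns:
                raise FormatError("column selector length mismatch")
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return AlignmentSet(
            ids=list(self.ids),
            matrix=self.matrix[:, idx].copy(),
            mask=None if self.mask is None else self.mask[idx].copy(),
            taxonomy=None if self.taxonomy is None else dict(self.taxonomy),
            col_origin=self.col_origin[idx].copy(),
        )

    def subset_sequences(self, ids: Iterable[str]) -> "AlignmentSet":
        ids = list(ids)
        rows = [self.index_of(i) for i in ids]
        return AlignmentSet(
            ids=ids,
            matrix=self.matrix[rows].copy(),
            mask=None if self.mask is None else self.mask.copy(),
            taxonomy=None
            if self.taxonomy is None
            else {i: self.taxonomy[i] for i in ids if i in self.taxonomy},
            col_origin=self.col_origin.copy(),
        )

    def copy(self) -> "AlignmentSet":
        return AlignmentSet(
            ids=list(self.ids),
            matrix=self.matrix.copy(),
            mask=None if self.mask is None else self.mask.copy(),
            taxonomy=None if self.taxonomy is None else dict(self.taxonomy),
            col_origin=self.col_origin.copy(),
        )
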
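"""Candidate probe enumeration and the binary probe x sequence matrix.

Candidate probes are every distinct ungapped 10-mer in the training
sequences, ranked by conservation (how many OTUs contain the probe) and
cut to the top N.  Hybridization is modelled as exact forward-strand
substring matching on the degapped processed sequence, so the incidence
matrix is binary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .core import AlignmentSet, LEVELS
from .errors import FormatError, LabelingError

PROBE_LENGTH = 10
TOP_N = 1000

_MAGIC = "#mfps-probe-matrix\tv1"


@dataclass
class ProbeMatrix:
    """Binary incidence of probes over sequences plus encoded taxonomy.

    ``codes(level)`` returns a dense integer group code per sequence;
    codes are built from full lineage prefixes so groups nest across
    levels (every OTU lies inside exactly one genus, every genus inside
    exactly one phylum).
    """

    probes: list[str]
    incidence: np.ndarray  # uint8, shape (n_probes, n_sequences)
    seq_ids: list[str]
    tax_codes: dict[str, np.ndarray] = field(default_factory=dict)
    group_names: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.incidence.shape != (len(self.probes), len(self.seq_ids)):
            raise FormatError("incidence shape does not match probes x sequences")
        if len(set(self.probes)) != len(self.probes):
            raise FormatError("duplicate probes")

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def n_sequences(self) -> int:
        return len(self.seq_ids)

    @property
    def level_sizes(self) -> dict[str, int]:
        return {lvl: len(self.group_names[lvl]) for lvl in LEVELS}

    def codes(self, level: str) -> np.ndarray:
        return self.tax_codes[level]

    def subset_sequences(self, index) -> "ProbeMatrix":
        """Restrict to a subset of sequence columns (training subsets)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return ProbeMatrix(
            probes=list(self.probes),
            incidence=self.incidence[:, index].copy(),
            seq_ids=[self.seq_ids[i] for i in index],
            tax_codes={lvl: c[index].copy() for lvl, c in self.tax_codes.items()},
            group_names={lvl: list(v) for lvl, v in self.group_names.items()},
        )

    # -- serialization --------------------------------------------------

    def save(self, path) -> None:
        """Text format: magic line, JSON header, then probe rows of 0/1."""
        header = {
            "seq_ids": self.seq_ids,
            "tax_codes": {lvl: c.tolist() for lvl, c in self.tax_codes.items()},
            "group_names": self.group_names,
        }
        with open(path, "w") as fh:
            fh.write(_MAGIC + "\n")
            fh.write(json.dumps(header, sort_keys=True) + "\n")
            for p, row in zip(self.probes, self.incidence):
                fh.write(p + "\t" + "".join(map(str, row.tolist())) + "\n")

    @classmethod
    def load(cls, path) -> "ProbeMatrix":
        with open(path) as fh:
            magic = fh.readline().rstrip("\n")
            if magic != _MAGIC:
                raise FormatError(f"not a probe-matrix file: {path}")
            header = json.loads(fh.readline())
            probes, rows = [], []
            for line in fh:
                p, bits = line.rstrip("\n").split("\t")
                probes.append(p)
                rows.append(np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0"))
        incidence = (
            np.vstack(rows) if rows else np.zeros((0, len(header["seq_ids"])), np.uint8)
        )
        return cls(
            probes=probes,
            incidence=incidence.astype(np.uint8),
            seq_ids=header["seq_ids"],
            tax_codes={
                lvl: np.asarray(v, dtype=np.int64)
                for lvl, v in header["tax_codes"].items()
            },
            group_names=header["group_names"],
        )


# ---------------------------------------------------------------------------
# Candidate enumeration and ranking
# ---------------------------------------------------------------------------


def _kmers(s: str, k: int) -> set[str]:
    return {s[i : i + k] for i in range(len(s) - k + 1)}


def enumerate_candidates(aln: AlignmentSet, probe_length: int = PROBE_LENGTH) -> list[str]:
    """All distinct ungapped k-mers occurring in any training sequence.

    Returned sorted for determinism.  Sequences shorter than the probe
    length after degapping contribute nothing (with a warning).
    """
    out: set[str] = set()
    for sid in aln.ids:
        s = aln.degapped(sid)
        if len(s) < probe_length:
            warnings.warn(f"sequence {sid!r} shorter than probe length; skipped")
            continue
        out |= _kmers(s, probe_length)
    return sorted(out)


def conservation_rank(candidates: list[str], aln: AlignmentSet) -> dict[str, int]:
    """Number of distinct OTUs containing each candidate probe."""
    if aln.taxonomy is None:
        raise LabelingError(aln.ids)
    k = len(candidates[0]) if candidates else PROBE_LENGTH
    cand = set(candidates)
    otus_of: dict[str, set] = {p: set() for p in candidates}
    for sid in aln.ids:
        otu = aln.taxonomy[sid].key("otu")
        for kmer in _kmers(aln.degapped(sid), k):
            if kmer in cand:
                otus_of[kmer].add(otu)
    return {p: len(s) for p, s in otus_of.items()}


def filter_top(ranked: dict[str, int], n: int = TOP_N) -> list[str]:
    """Keep the ``n`` most conserved probes; boundary ties lexicographic."""
    if n < 1:
        raise ValueError("n must be >= 1")
    order = sorted(ranked, key=lambda p: (-ranked[p], p))
    return order[:n]


# ---------------------------------------------------------------------------
# Matrix construction
# ---------------------------------------------------------------------------


def _encode_taxonomy(aln: AlignmentSet) -> tuple[dict[str, np.ndarray], dict[str, list[str]]]:
    codes: dict[str, np.ndarray] = {}
    names: dict[str, list[str]] = {}
    for lvl in LEVELS:
        mapping: dict[tuple, int] = {}
        arr = np.empty(aln.n_sequences, dtype=np.int64)
        for i, sid in enumerate(aln.ids):
            key = aln.taxonomy[sid].key(lvl)
            arr[i] = mapping.setdefault(key, len(mapping))
        codes[lvl] = arr
        names[lvl] = ["|".join(k) for k in mapping]
    return codes, names


def build_matrix(
    probes: list[str], aln: AlignmentSet, reverse_complement: bool = False
) -> ProbeMatrix:
    """Exact-substring incidence matrix with encoded taxonomy.

    ``reverse_complement=True`` additionally scores a probe as bound when
    its reverse complement occurs in the sequence (off by default: the
    hybridization model is forward-strand substring occurrence).
    """
    if not probes:
        raise ValueError("probes must be non-empty")
    if aln.taxonomy is None:
        raise LabelingError(aln.ids)
    k = len(probes[0])
    probe_index = {p: j for j, p in enumerate(probes)}
    incidence = np.zeros((len(probes), aln.n_sequences), dtype=np.uint8)
    for i, sid in enumerate(aln.ids):
        kmers = _kmers(aln.degapped(sid), k)
        for kmer in kmers:
            j = probe_index.get(kmer)
            if j is not None:
                incidence[j, i] = 1
            if reverse_complement:
                j = probe_index.get(str(Seq(kmer).reverse_complement()))
                if j is not None:
                    incidence[j, i] = 1
    codes, names = _encode_taxonomy(aln)
    return ProbeMatrix(
        probes=list(probes),
        incidence=incidence,
        seq_ids=list(aln.ids),
        tax_codes=codes,
        group_names=names,
    )


def build_training_matrix(
    aln: AlignmentSet,
    probe_length: int = PROBE_LENGTH,
    top_n: int | None = TOP_N,
    reverse_complement: bool = False,
) -> ProbeMatrix:
    """Enumerate, rank, cut to top-N (``top_n=None`` keeps all) and build."""
    candidates = enumerate_candidates(aln, probe_length)
    ranked = conservation_rank(candidates, aln)
    if top_n is not None:
        candidates = filter_top(ranked, top_n)
    return build_matrix(candidates, aln, reverse_complement=reverse_complement)
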
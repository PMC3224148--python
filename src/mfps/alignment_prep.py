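"""Sequence-level training-data preparation.

Stages, in pipeline order: read a gapped FASTA (optionally containing a
column-mask record), drop hypervariable columns via the mask, locate the
two conserved primer regions, truncate the alignment ten ungapped
positions inward of the primers, and apply quality filtering (too-short,
ambiguous bases, exact duplicates).

Conventions: alignment columns are 0-based, intervals half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .core import GAP, GAP_CHAR, AlignmentSet, TaxonomyLabel
from .errors import EmptyTargetError, FormatError, PrimerNotFoundError

log = logging.getLogger(__name__)

#: Conserved bacterial 16S primers used to delimit the probe target region.
FWD_PRIMER_27F = "AGAGTTTGATCMTGGCTCAG"
REV_PRIMER_1392R = "ACGGGCGGTGTGTRC"

#: Characters in a mask record that mean "drop this column".
MASK_DROP_CHARS = frozenset("0-.")

#: Default id prefixes identifying a mask record.
MASK_ID_PREFIXES = ("#=GC", "mask")

AMBIGUOUS = set("MRWSYKVHDBN")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_aligned_fasta(path, mask_id: str | None = None) -> AlignmentSet:
    """Read an aligned FASTA; split out a mask record if ``mask_id`` matches.

    A record whose id equals or starts with ``mask_id`` is interpreted as
    the column mask: characters in ``{0, -, .}`` mark columns to drop,
    anything else marks columns to keep.
    """
    records, mask = [], None
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if mask_id is not None and (rec.id == mask_id or rec.id.startswith(mask_id)):
            if mask is not None:
                raise FormatError("multiple mask records found")
            mask = np.array([c not in MASK_DROP_CHARS for c in seq], dtype=bool)
            continue
        records.append((rec.id, seq))
    if not records:
        raise FormatError(f"no sequence records in {path}")
    aln = AlignmentSet.from_strings(records, mask=mask)
    if mask is not None and mask.size != aln.n_columns:
        raise FormatError("mask length does not match alignment width")
    return aln


def write_aligned_fasta(aln: AlignmentSet, path, mask_id: str = "mask") -> None:
    """Write the alignment; a mask, if present, becomes the first record."""
    with open(path, "w") as fh:
        if aln.mask is not None:
            mask_str = "".join("1" if k else "0" for k in aln.mask)
            fh.write(f">{mask_id}\n{mask_str}\n")
        for sid, seq in aln.iter_sequences():
            fh.write(f">{sid}\n{seq}\n")


def read_taxonomy_tsv(path) -> dict[str, TaxonomyLabel]:
    """Read ``id<TAB>phylum<TAB>genus[<TAB>otu]`` rows (no header)."""
    out: dict[str, TaxonomyLabel] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"taxonomy row needs >=3 fields: {line!r}")
            sid, phylum, genus = parts[:3]
            otu = parts[3] if len(parts) > 3 and parts[3] else None
            if sid in out:
                raise FormatError(f"duplicate taxonomy id: {sid}")
            out[sid] = TaxonomyLabel(phylum=phylum, genus=genus, otu=otu)
    return out


def write_taxonomy_tsv(taxonomy: dict[str, TaxonomyLabel], path) -> None:
    with open(path, "w") as fh:
        for sid, lab in taxonomy.items():
            otu = lab.otu or ""
            fh.write(f"{sid}\t{lab.phylum}\t{lab.genus}\t{otu}\n")


# ---------------------------------------------------------------------------
# Hypervariable-region removal
# ---------------------------------------------------------------------------


def remove_hypervariable(aln: AlignmentSet) -> AlignmentSet:
    """Drop all columns the mask marks hypervariable.

    Returns a copy containing only keep columns; the new mask is all-True
    of the new width.  Requires a mask.
    """
    if aln.mask is None:
        raise ValueError("remove_hypervariable requires a column mask")
    out = aln.select_columns(aln.mask)
    out.mask = np.ones(out.n_columns, dtype=bool)
    return out


# ---------------------------------------------------------------------------
# Primer location
# ---------------------------------------------------------------------------


def _iupac_regex(primer: str) -> re.Pattern:
    parts = []
    for c in primer.upper():
        opts = ambiguous_dna_values.get(c)
        if opts is None:
            raise ValueError(f"not an IUPAC DNA code: {c!r}")
        parts.append(c if len(opts) == 1 else f"[{opts}]")
    return re.compile("".join(parts))


def iupac_match(primer: str, target: str) -> bool:
    """True when ``target`` matches ``primer`` exactly under IUPAC degeneracy."""
    return bool(_iupac_regex(primer).fullmatch(target.upper()))


def find_primer_region(
    aln: AlignmentSet, primer: str, orientation: str = "forward"
) -> tuple[int, int]:
    """Locate the alignment column interval of a conserved primer site.

    The primer (reverse orientation: its reverse complement) is searched
    in each sequence's degapped string under IUPAC degeneracy; a column
    interval qualifies when at least half the sequences carry an exact
    match spanning exactly those columns.  Ties are broken leftmost for
    forward primers and rightmost for reverse primers.
    """
    if aln.n_sequences == 0:
        raise ValueError("empty alignment")
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"orientation must be forward|reverse: {orientation!r}")
    target = primer if orientation == "forward" else str(Seq(primer).reverse_complement())
    rx = _iupac_regex(target)

    votes: dict[tuple[int, int], int] = {}
    for i in range(aln.n_sequences):
        row = aln.matrix[i]
        nongap = np.flatnonzero(row != GAP)
        s = row[nongap].tobytes().decode("ascii")
        seen: set[tuple[int, int]] = set()
        for m in rx.finditer(s):
            cols = (int(nongap[m.start()]), int(nongap[m.end() - 1]) + 1)
            seen.add(cols)
        for cols in seen:
            votes[cols] = votes.get(cols, 0) + 1

    need = -(-aln.n_sequences // 2)  # ceil(n/2): a majority
    qualifying = [iv for iv, n in votes.items() if n >= need]
    if not qualifying:
        raise PrimerNotFoundError(f"primer {primer!r} not found ({orientation})")
    qualifying.sort()
    return qualifying[0] if orientation == "forward" else qualifying[-1]


# ---------------------------------------------------------------------------
# Truncation
# ---------------------------------------------------------------------------


def truncation_interval(
    aln: AlignmentSet, fwd: tuple[int, int], rev: tuple[int, int], inset: int = 10
) -> tuple[int, int]:
    """Columns retained after trimming ``inset`` ungapped consensus
    positions inward of each primer region (primer columns removed).

    Inset counting is done on the ungapped consensus: the retained region
    starts just after the ``inset``-th ungapped consensus position
    following the forward primer and ends just before the ``inset``-th
    ungapped position preceding the reverse primer.
    """
    if fwd[1] > rev[0]:
        raise ValueError(f"forward primer must precede reverse: {fwd} vs {rev}")
    cons = aln.consensus()
    ungapped_cols = np.flatnonzero(cons != GAP)

    after = ungapped_cols[ungapped_cols >= fwd[1]]
    before = ungapped_cols[ungapped_cols < rev[0]]
    if inset == 0:
        start, end = fwd[1], rev[0]
    else:
        if after.size < inset or before.size < inset:
            raise EmptyTargetError("inset exceeds the inter-primer region")
        start = int(after[inset - 1]) + 1
        end = int(before[-inset])
    if start >= end:
        raise EmptyTargetError("no target columns remain after inset truncation")
    return start, end


def truncate_to_primers(
    aln: AlignmentSet, fwd: tuple[int, int], rev: tuple[int, int], inset: int = 10
) -> AlignmentSet:
    """Restrict the alignment to the primer-delimited target region."""
    start, end = truncation_interval(aln, fwd, rev, inset)
    return aln.select_columns(np.arange(start, end))


# ---------------------------------------------------------------------------
# Quality filtering
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    n_input: int = 0
    n_too_short: int = 0
    n_ambiguous: int = 0
    n_duplicate: int = 0
    n_kept: int = 0


def qc_filter(
    aln: AlignmentSet,
    fwd: tuple[int, int],
    rev: tuple[int, int],
    inset: int = 10,
    report: QCReport | None = None,
) -> AlignmentSet:
    """Truncate to the primer-delimited region and filter sequences.

    Removal rules, applied in order:

    1. too short — the truncated alignment has an end gap on a side whose
       truncated-away flank contained only gaps (i.e. the sequence never
       reached the retained region from that side).  A side with no
       truncated columns provides no evidence and never triggers the rule.
    2. ambiguous — any character outside ``{A, C, G, T, -}``.
    3. duplicate — degapped truncated string identical to that of an
       earlier (kept) sequence; the first occurrence wins.
    """
    start, end = truncation_interval(aln, fwd, rev, inset)
    rep = report if report is not None else QCReport()
    rep.n_input = aln.n_sequences

    keep_ids: list[str] = []
    seen: set[str] = set()
    allowed = frozenset(b"ACGT-")
    for i, sid in enumerate(aln.ids):
        row = aln.matrix[i]
        lead, body, tail = row[:start], row[start:end], row[end:]
        short = False
        if start > 0 and body[0] == GAP and bool((lead == GAP).all()):
            short = True
        if end < aln.n_columns and body[-1] == GAP and bool((tail == GAP).all()):
            short = True
        if short:
            rep.n_too_short += 1
            continue
        if any(b not in allowed for b in body.tobytes()):
            rep.n_ambiguous += 1
            continue
        degapped = body[body != GAP].tobytes().decode("ascii")
        if degapped in seen:
            rep.n_duplicate += 1
            continue
        seen.add(degapped)
        keep_ids.append(sid)

    rep.n_kept = len(keep_ids)
    if rep.n_kept == 0:
        log.warning("qc_filter removed every sequence")
    log.info(
        "qc_filter: %d in, %d too short, %d ambiguous, %d duplicate, %d kept",
        rep.n_input, rep.n_too_short, rep.n_ambiguous, rep.n_duplicate, rep.n_kept,
    )
    out = aln.select_columns(np.arange(start, end))
    return out.subset_sequences(keep_ids)


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


@dataclass
class PrepConfig:
    """Knobs for the sequence-preparation stage.

    ``original_pipeline`` reproduces the legacy behaviour in which the
    hypervariable columns are left in place (the mask is ignored).
    """

    fwd_primer: str = FWD_PRIMER_27F
    rev_primer: str = REV_PRIMER_1392R
    inset: int = 10
    original_pipeline: bool = False


def prepare(
    aln: AlignmentSet, config: PrepConfig | None = None, report: QCReport | None = None
) -> AlignmentSet:
    """Run mask removal (unless disabled), primer truncation and QC."""
    cfg = config or PrepConfig()
    if not cfg.original_pipeline:
        aln = remove_hypervariable(aln)
    fwd = find_primer_region(aln, cfg.fwd_primer, "forward")
    rev = find_primer_region(aln, cfg.rev_primer, "reverse")
    return qc_filter(aln, fwd, rev, inset=cfg.inset, report=report)
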
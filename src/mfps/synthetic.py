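"""Synthetic aligned 16S-like training sets with planted taxonomy.

Sequences evolve on a star phylogeny per level (root -> phylum ancestor
-> genus ancestor -> OTU ancestor -> sequence) by independent per-column
substitutions, giving the nested similarity structure the probe-design
method assumes.  Two conserved primer sites are planted verbatim at the
alignment ends, hypervariable blocks mutate at an elevated rate and are
the only place gaps occur, and a mask record marks them for removal, so
the full preparation pipeline is exercised end to end.

Leaf divergence from the OTU ancestor is capped at half the within-OTU
budget per sequence, which guarantees every within-OTU pairwise distance
outside the hypervariable blocks stays at or below the budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .core import BASES, GAP, AlignmentSet, TaxonomyLabel
from .errors import InvalidSpecError, ProbeCollisionError

_BASE_ARR = np.frombuffer(BASES.encode(), dtype=np.uint8)


def _concrete(iupac: str) -> str:
    """Replace degenerate codes with their first expansion (deterministic)."""
    from Bio.Data.IUPACData import ambiguous_dna_values

    return "".join(ambiguous_dna_values[c][0] for c in iupac)


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape and divergence structure of a synthetic training set.

    Divergences are fractions of eligible (conserved, non-primer)
    columns.  ``within_otu_divergence`` bounds the pairwise distance of
    sequences inside one OTU and must not exceed 0.01 so planted OTUs
    respect the 99% clustering threshold; between-level divergences must
    increase with taxonomic distance.
    """

    n_phyla: int = 3
    genera_per_phylum: int = 3
    otus_per_genus: int = 4
    seqs_per_otu: int = 5
    alignment_length: int = 800
    hypervariable_blocks: tuple[tuple[int, int], ...] = ((200, 280), (520, 600))
    within_otu_divergence: float = 0.008
    between_group_divergence: Mapping[str, float] = field(
        default_factory=lambda: {"otu": 0.03, "genus": 0.08, "phylum": 0.16}
    )
    gap_rate: float = 0.05
    hypervariable_rate: float = 0.25
    fwd_primer: str = "AGAGTTTGATCMTGGCTCAG"
    rev_primer: str = "ACGGGCGGTGTGTRC"
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_phyla, self.genera_per_phylum, self.otus_per_genus, self.seqs_per_otu)
        if any(c < 1 for c in counts):
            raise InvalidSpecError(f"all counts must be >= 1, got {counts}")
        if not (0 <= self.within_otu_divergence <= 0.01):
            raise InvalidSpecError("within_otu_divergence must lie in [0, 0.01]")
        d = self.between_group_divergence
        if not (self.within_otu_divergence < d["otu"] <= d["genus"] <= d["phylum"]):
            raise InvalidSpecError(
                "divergences must be ordered: within-OTU < otu <= genus <= phylum"
            )
        for lo, hi in self.hypervariable_blocks:
            if not (0 <= lo < hi <= self.alignment_length):
                raise InvalidSpecError(f"hypervariable block out of range: ({lo}, {hi})")
            if lo < len(self.fwd_primer) or hi > self.alignment_length - len(self.rev_primer):
                raise InvalidSpecError("hypervariable block overlaps a primer site")

    @property
    def n_sequences(self) -> int:
        return self.n_phyla * self.genera_per_phylum * self.otus_per_genus * self.seqs_per_otu


def generate_taxonomy(spec: SyntheticSpec) -> list[TaxonomyLabel]:
    """One label per sequence, nested P{p} > G{p}.{g} > OTU{o}."""
    spec.validate()
    labels = []
    for p in range(spec.n_phyla):
        for g in range(spec.genera_per_phylum):
            for o in range(spec.otus_per_genus):
                lab = TaxonomyLabel(
                    phylum=f"P{p + 1}",
                    genus=f"G{p + 1}.{g + 1}",
                    otu=f"OTU{o + 1}",
                )
                labels.extend([lab] * spec.seqs_per_otu)
    return labels


def _mutate(rng: np.random.Generator, seq: np.ndarray, columns: np.ndarray, n: int) -> np.ndarray:
    """Substitute ``n`` distinct columns (drawn from ``columns``) to a
    different base; returns a copy."""
    out = seq.copy()
    if n == 0 or columns.size == 0:
        return out
    n = min(n, columns.size)
    cols = rng.choice(columns, size=n, replace=False)
    for c in cols:
        others = _BASE_ARR[_BASE_ARR != out[c]]
        out[c] = rng.choice(others)
    return out


def generate_alignment(spec: SyntheticSpec, labels: Sequence[TaxonomyLabel]) -> AlignmentSet:
    """Gapped alignment with mask, primer sites and planted taxonomy."""
    spec.validate()
    if len(labels) != spec.n_sequences:
        raise InvalidSpecError("labels do not match the spec's sequence count")
    rng = np.random.default_rng(spec.seed)
    L = spec.alignment_length

    hv = np.zeros(L, dtype=bool)
    for lo, hi in spec.hypervariable_blocks:
        hv[lo:hi] = True

    fwd = _concrete(spec.fwd_primer)
    rev_site = str(Seq(_concrete(spec.rev_primer)).reverse_complement())
    primer_cols = np.zeros(L, dtype=bool)
    primer_cols[: len(fwd)] = True
    primer_cols[L - len(rev_site) :] = True

    eligible = np.flatnonzero(~hv & ~primer_cols)
    hv_cols = np.flatnonzero(hv)
    n_elig = eligible.size

    m_phylum = round(spec.between_group_divergence["phylum"] * n_elig)
    m_genus = round(spec.between_group_divergence["genus"] * n_elig)
    m_otu = round(spec.between_group_divergence["otu"] * n_elig)
    m_within = int(spec.within_otu_divergence / 2 * n_elig)

    root = _BASE_ARR[rng.integers(4, size=L)]
    root[: len(fwd)] = np.frombuffer(fwd.encode(), dtype=np.uint8)
    root[L - len(rev_site) :] = np.frombuffer(rev_site.encode(), dtype=np.uint8)

    rows, ids, taxonomy = [], [], {}
    idx = 0
    for p in range(spec.n_phyla):
        phy_anc = _mutate(rng, root, eligible, m_phylum)
        for g in range(spec.genera_per_phylum):
            gen_anc = _mutate(rng, phy_anc, eligible, m_genus)
            for o in range(spec.otus_per_genus):
                otu_anc = _mutate(rng, gen_anc, eligible, m_otu)
                for _ in range(spec.seqs_per_otu):
                    seq = _mutate(rng, otu_anc, eligible, m_within)
                    # hypervariable blocks: fast substitution, then gaps
                    if hv_cols.size:
                        flip = hv_cols[rng.random(hv_cols.size) < spec.hypervariable_rate]
                        seq = _mutate(rng, seq, flip, flip.size) if flip.size else seq
                        gaps = hv_cols[rng.random(hv_cols.size) < spec.gap_rate]
                        seq[gaps] = GAP
                    sid = f"seq{idx:04d}"
                    rows.append(seq)
                    ids.append(sid)
                    taxonomy[sid] = labels[idx]
                    idx += 1

    return AlignmentSet(
        ids=ids,
        matrix=np.vstack(rows),
        mask=~hv,
        taxonomy=taxonomy,
    )


def generate(spec: SyntheticSpec) -> AlignmentSet:
    """Convenience: taxonomy + alignment in one call."""
    return generate_alignment(spec, generate_taxonomy(spec))


# ---------------------------------------------------------------------------
# Probe planting
# ---------------------------------------------------------------------------


def plant_discriminative_probes(
    aln: AlignmentSet,
    probes: Sequence[str],
    placement: str = "otu",
    region: tuple[int, int] | None = None,
    window_spacing: int = 2,
) -> tuple[AlignmentSet, dict[str, tuple[tuple[str, ...], int]]]:
    """Embed each probe in all sequences of exactly one group.

    Probe i is written into a dedicated gap-free window of kept columns
    for group i (groups at ``placement`` level, in order of first
    appearance).  Returns the modified copy and, per probe, the target
    group key and the window's start column.  Raises if any probe ends up
    occurring (as a degapped substring) outside its group.
    """
    if not probes:
        return aln.copy(), {}
    if any(set(p) - set("ACGT") for p in probes):
        raise InvalidSpecError("probes must contain only A/C/G/T")
    if aln.taxonomy is None:
        raise InvalidSpecError("alignment has no taxonomy to place probes against")
    plen = len(probes[0])
    if any(len(p) != plen for p in probes):
        raise InvalidSpecError("probes must share one length")

    groups: list[tuple[str, ...]] = []
    members: dict[tuple[str, ...], list[int]] = {}
    for i, sid in enumerate(aln.ids):
        key = aln.taxonomy[sid].key(placement)
        if key not in members:
            groups.append(key)
            members[key] = []
        members[key].append(i)
    if len(probes) > len(groups):
        raise InvalidSpecError(
            f"{len(probes)} probes but only {len(groups)} groups at level {placement!r}"
        )

    lo, hi = region if region is not None else (40, aln.n_columns - 40)
    keep = aln.mask if aln.mask is not None else np.ones(aln.n_columns, dtype=bool)
    usable = np.flatnonzero(keep[lo:hi]) + lo
    # carve non-overlapping windows out of contiguous runs of kept columns
    windows: list[int] = []
    run_start, prev = None, None
    step = plen + window_spacing
    for c in usable:
        if run_start is None:
            run_start = prev = int(c)
            continue
        if c == prev + 1:
            prev = int(c)
        else:
            windows.extend(range(run_start, prev - plen + 2, step))
            run_start = prev = int(c)
    if run_start is not None:
        windows.extend(range(run_start, prev - plen + 2, step))
    if len(windows) < len(probes):
        raise InvalidSpecError(
            f"only {len(windows)} probe windows available for {len(probes)} probes"
        )

    out = aln.copy()
    placements: dict[str, tuple[tuple[str, ...], int]] = {}
    for i, probe in enumerate(probes):
        w = windows[i]
        rows = members[groups[i]]
        out.matrix[np.ix_(rows, range(w, w + plen))] = np.frombuffer(
            probe.encode(), dtype=np.uint8
        )
        placements[probe] = (groups[i], w)

    # exclusivity check on degapped sequences
    for probe, (group, _) in placements.items():
        target = set(members[group])
        for i, sid in enumerate(out.ids):
            present = probe in out.degapped(sid)
            if present and i not in target:
                raise ProbeCollisionError(
                    f"probe {probe!r} for group {group} also occurs in {sid!r}"
                )
            if not present and i in target:
                raise ProbeCollisionError(
                    f"probe {probe!r} failed to embed in {sid!r} of group {group}"
                )
    return out, placements


def random_probes(
    n: int,
    length: int,
    rng: np.random.Generator,
    avoid_kmers: frozenset[str] | set[str] = frozenset(),
) -> list[str]:
    """Random distinct A/C/G/T strings for planting.

    ``avoid_kmers`` rejects candidates already present somewhere (pass the
    alignment's k-mer content to avoid accidental background collisions).
    """
    out: set[str] = set()
    while len(out) < n:
        cand = "".join(BASES[i] for i in rng.integers(4, size=length))
        if cand not in avoid_kmers:
            out.add(cand)
    return sorted(out)


def _all_kmers(aln: AlignmentSet, k: int) -> set[str]:
    out: set[str] = set()
    for sid in aln.ids:
        s = aln.degapped(sid)
        out.update(s[i : i + k] for i in range(len(s) - k + 1))
    return out


def plant_random(
    aln: AlignmentSet,
    placement: str,
    rng: np.random.Generator,
    length: int = 10,
) -> tuple[AlignmentSet, dict[str, tuple[tuple[str, ...], int]]]:
    """Plant one fresh random probe per group at ``placement`` level.

    Probes are screened against the alignment's existing k-mer content so
    they can only occur where planted (up to rare chimeras at window
    boundaries, which the planting check still catches).
    """
    n_groups = len({lab.key(placement) for lab in aln.taxonomy.values()})
    probes = random_probes(n_groups, length, rng, avoid_kmers=_all_kmers(aln, length))
    return plant_discriminative_probes(aln, probes, placement=placement)
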
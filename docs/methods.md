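# Methods

## Hybridization model and objectives

A probe is assumed to hybridize to a gene exactly when the probe string
is a forward-strand substring of the gene's degapped, processed
sequence; hybridization is therefore binary and the fingerprint of a
sequence under a k-probe set is a k-bit vector.  No thermodynamics,
mismatches or reverse-complement binding are modelled (reverse-complement
matching exists behind a flag, off by default).

Probe sets are scored by the multi-level fidelity cost

    C = 1/2 Σ_f Σ_i P_i γ_{i,f} (γ_{i,f} − 1),

summing over distinct fingerprints f and taxonomic levels i ∈ {OTU,
genus, phylum}.  γ_{i,f} counts the groups at level i containing at
least one sequence with fingerprint f; each pair of groups conflated by
f costs P_i.  Group identity is the full lineage prefix, so groups nest
(an OTU lies in exactly one genus, a genus in one phylum); a consequence
used throughout is the HFR nesting inequality (below).  The legacy
distinguishing objective C = 1/2 Σ_f n_f (n_f − 1) (n_f = sequences
bearing f) is the special case obtained by making every sequence its own
OTU with penalties (1, 0, 0); a test asserts this identity exactly.
The published statement of the legacy objective is verbal ("all
undistinguished clones are equally undesirable"); the
pairs-of-undistinguished-sequences form used here is our reading of it.

Default penalties are (P_OTU, P_genus, P_phylum) = (1, 30, 0).  The
phylum penalty defaults to zero because phylum fidelity follows from
OTU/genus fidelity via nesting; the genus penalty trades OTU fidelity
for genus fidelity as it grows (visible in the penalty sweep), and 30 is
the configuration the method's authors selected for full-scale data.
At desk scale (small k relative to the OTU count) the trade-off is
sharper: with k = 10 the genus-30 configuration buys genus HFR = 1.0 at
a real cost in OTU HFR, so the method comparison evaluates the
OTU-penalty-only configuration at the OTU level and the genus-30
configuration at the genus level — matching how the two configurations
are meant to be used.

## Simulated annealing

The optimizer performs single-swap moves: a uniformly random non-retained
member is replaced by a uniformly random probe outside the set (and not
on the avoid list), accepted by the Metropolis rule.  Choices with no
published prescription, fixed here:

- initial temperature: calibrated per run so ~80% of uphill moves would
  be accepted, estimated from 200 trial moves at the initial state
  (fallback 1.0 if no uphill move is seen);
- cooling: geometric, factor 0.995 per move;
- moves per run: 200·k unless overridden;
- restarts: 10 independent runs (restart r seeds its generator with
  seed + r), best final cost wins, ties to the lowest restart index;
  a run that reaches cost 0 stops early (0 is the global minimum);
- fingerprints are bit-packed (ceil(k/8) bytes per sequence); a swap
  updates the packed matrix by XOR, which is bit-identical to repacking
  from scratch (property-tested), and a cost evaluation is a byte-string
  uniqueness pass plus per-level group counting.

## Training-data preparation

Inputs are pre-aligned, gapped sequences; columns are 0-based with
half-open intervals.  Stages, in order:

1. **Hypervariable removal.**  A mask record (id prefix "mask" or
   "#=GC"; characters 0, '-', '.' mean drop) selects columns to keep.
   Probes from hypervariable columns would be informative only for
   narrow taxa, so the columns are removed before anything else.  The
   legacy-pipeline mode skips this stage.
2. **Primer location.**  The conserved primer sites (defaults 27F
   AGAGTTTGATCMTGGCTCAG and 1392R ACGGGCGGTGTGTRC) are found by exact
   IUPAC-degenerate matching in each sequence's degapped string; a
   column interval qualifies when ≥50% of sequences match it exactly
   (ties: leftmost for forward, rightmost for reverse; the reverse
   primer is matched as its reverse complement).
3. **Truncation.**  Ten ungapped consensus positions are trimmed inward
   of each primer region ("nucleotide positions" are sequence, not
   column, coordinates; the consensus maps them back to columns).
4. **QC.**  Rules applied in order: (a) too short — the truncated
   alignment has an end gap on a side whose truncated-away flank was all
   gaps (a side with no truncated columns provides no evidence, which
   makes the filter idempotent); (b) any non-A/C/G/T/gap character;
   (c) duplicate of an earlier sequence's degapped truncated string
   (first wins).  Whether deduplication precedes or follows truncation
   is not prescribed anywhere; deduplicating after region handling is a
   choice, made because the regions kept determine which sequences are
   distinguishable at all.

## OTU clustering and the probe matrix

Pairwise distance is mismatches over comparable columns; columns gapped
in both sequences are ignored, gap-versus-base counts one mismatch per
column (adjacent gap columns count individually).  The distance formula
of the external tool historically used for this step is not documented;
this policy is declared, not inferred.  Clustering is complete-linkage,
cut at 0.01, run independently per genus; complete linkage is what makes
"minimum within-OTU similarity of 99%" hold literally (the maximum
within-cluster distance is bounded by the cut).  Merges break ties by
the lexicographically smallest pair of cluster representatives and OTU
ids follow input order, so results are deterministic; a test checks the
partition against SciPy's complete-linkage on tie-free inputs.

Candidate probes are every distinct ungapped 10-mer in the processed
sequences, ranked by the number of distinct OTUs each occurs in, cut to
the top 1000 (ties at the boundary resolved lexicographically — the
boundary rule is ours).  Homopolymer-containing probes are not filtered.
The incidence matrix stores one 0/1 per probe × sequence, with taxonomy
encoded as dense nested integer codes; serialization is a plain-text
header-plus-rows format that round-trips bit-exactly.

## Evaluation

The High Fidelity Ratio at level i is the fraction of distinct
fingerprints with γ_{i,f} = 1.  Because groups nest, HFR_OTU ≤
HFR_genus ≤ HFR_phylum on any input (property-tested on 200 randomized
instances).  The distance histogram takes, per low-fidelity distinct
fingerprint (judged at the OTU level by default; genus behind a flag),
the average pairwise distance of its sequences, binned at 1%, averaged
with SD across probe sets.  High-fidelity fingerprints cannot exceed the
1% bin when OTUs come from complete-linkage clustering at 1% on the same
distances; the computed maximum is exposed and asserted in tests.

Cross-validation uses the 20%-train / 100%-validate design: five
disjoint simple random samples (no stratification), each training one
probe set that is scored on all sequences.  Phylum holdout trains with
one phylum's sequences removed and evaluates on everything.  Random
controls sample probe sets uniformly from the (conservation-ranked)
matrix.  Positional bias reports each probe's first match start on the
degapped consensus of the processed alignment (falling back to the first
matching sequence); the coordinate system is this package's processed-
alignment coordinate, not a reference-genome position.  Replicate counts
default to 100 probe sets per condition and scale down via config; the
packaged experiments and acceptance script use 10–20 sets per condition
and k ∈ {10, 20, 36} on the synthetic study below, sizes at which every
qualitative contrast is already unambiguous.

## Synthetic data

The generator emulates the structure the method relies on, not real 16S
evolution.  Sequences evolve on a star phylogeny per level (root →
phylum → genus → OTU → leaf) by independent per-column substitutions on
the eligible columns (everything outside primer sites and hypervariable
blocks), with defaults 3 phyla × 3 genera/phylum × 4 OTUs/genus × 5
sequences/OTU, 800 columns, two 80-column hypervariable blocks, and
divergences 0.16 / 0.08 / 0.03 between phyla / genera / OTUs.  Each leaf
mutates at most ⌊w/2 · n_eligible⌋ eligible columns (w = within-OTU
budget, default 0.008), which *guarantees* every within-OTU pairwise
distance outside hypervariable blocks stays ≤ w, so planted OTUs always
respect the 99% threshold.  Hypervariable columns mutate at an elevated
rate (0.25) and are the only place gaps occur (rate 0.05); the mask
marks exactly these blocks.  Primer sites are planted verbatim
(degenerate codes concretized to their first expansion) and held fixed.

Discriminative probes can be planted one per group at a chosen level:
each probe is written into its own window of kept columns for the target
group's sequences, candidate probes are screened against the alignment's
existing 10-mer content, and planting verifies exclusivity (a collision
raises).  Everything is a pure function of the spec and seed.

What this does not model: indels outside hypervariable blocks, rate
heterogeneity beyond the two classes, chimeras, sequencing error,
realistic base composition, or overlap of taxonomic signals between
levels.  Passing tests therefore demonstrate correctness of the
algorithms and the claimed qualitative contrasts under clean nested
structure — not performance on real RDP-scale data, whose absolute HFR
values depend on a dated database snapshot.

## Known limitations

- Under unstratified 20% training samples, cross-validated OTU HFR on
  the synthetic study cannot reach 1.0: a training fold that never saw
  an OTU exerts no pressure to give it a unique fingerprint.  Training-
  fold fidelity is perfect (annealing reaches cost 0) and full-data HFR
  beats the random control, which is what the tests assert.
- Exact-substring hybridization ignores single-mismatch binding, which
  real 10-mer hybridizations exhibit; this is inherent to the objective
  implemented.
- The annealing schedule is heuristic; optimality is verified only on
  enumerable instances (exhaustive search over all C(12,3) subsets).
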
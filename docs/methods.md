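# Methods

This note documents the models implemented by `hfbscan`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical corner cases.

## Hydrophobin mining by cysteine-spacing grammars

A `CysGrammar` constrains a protein's cysteine skeleton: a leader range
(residues before the first skeleton Cys), seven ordered gap ranges
(residues strictly between consecutive skeleton Cys; the two adjacent
"CC" doublets are fixed 0-length gaps), and a tail range. Gaps may not
contain letters in `forbid_in_gaps` (default `{C}`; a "strict-X" mode
adds `W`, since some published strain patterns define X as excluding both
cysteine and tryptophan — the biological rationale for excluding W is
unclear, so it is opt-in).

Classification of a protein proceeds as:

1. length filter: candidates must be 80–400 aa (class I HFBs are small;
   the upper bound admits long-leader variants short of polyhydrophobins);
2. the narrow class II consensus grammar
   (`C-X9–10-CC-X11-C-X16-C-X8–9-CC-X10-C`) is tested first: a sequence
   satisfying it is called `class_II`;
3. otherwise the broad "typical" pattern
   (`X2–38-C-X5–9-CC-X11–44-C-X8–23-C-X5–9-CC-X6–18-C-X2–14`) is tested
   and a match is called `typical_class_I`. The typical pattern — not the
   tighter literature class I consensus (`C-X6–7-CC-X33–41-…`) — is the
   primary filter because real basidiomycete class I spacings (e.g. a
   13-residue gap between Cys3 and Cys4) routinely fall outside the
   consensus ranges;
4. right-length sequences with 6, 7 or 9 cysteines that cannot satisfy
   the typical grammar are `atypical` hydrophobin-like candidates (such
   reduced-skeleton HFBs are repeatedly reported in the literature);
5. everything else is `rejected` with a reason (`length`, `cys_count`, or
   `no_grammar_match`).

Classification is grammar-only: hydropathy is reported alongside by the
physchem module but never used as a secondary classification signal,
keeping the verdict auditable against the matched gap vector.

With more than 8 cysteines, 8-subsets of the Cys positions are enumerated
in lexicographic order (which visits smaller leaders first) up to a cap
of 5,000 combinations; beyond the cap the matcher refuses and flags
`cap_exceeded`, so behavior on pathological Cys-rich inputs is bounded
and deterministic. The matcher is tested for exact agreement with a
brute-force enumeration oracle on random sequences up to 300 aa / 12 Cys.

An optional annotation table (signal peptide, subcellular location) can
be merged into the screening report; these predictions come from external
tools, are never computed here, and default to "unknown".

## Physicochemical descriptors

- **Molecular weight**: sum of average (not monoisotopic) residue masses
  plus one water (18.01524 Da), matching how 2-decimal protein MWs are
  conventionally reported.
- **GRAVY**: mean Kyte–Doolittle hydropathy over the chain; the sliding
  `hydropathy_profile` uses an unweighted window mean, default window 9
  (a common choice for detecting surface-seeking segments; any odd window
  ≤ length is accepted).
- **Theoretical pI**: the root of the Henderson–Hasselbalch net-charge
  function, found by bisection on (0, 14) until |charge| < 1e−4. The pKa
  set is the Bjellqvist table as used by the classic ProtParam service:
  side chains D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0; flat
  C-terminal pKa 3.55; residue-specific N-terminal pKas (A 7.59, M 7.0,
  S 6.93, P 8.36, T 6.82, V 7.44, E 7.7) with default 7.5. The net charge
  is strictly decreasing in pH, so the root is unique. The table is
  overridable via `PkaTable`.
- **Charge counts**: negatives = D+E, positives = K+R; histidine is
  excluded on both sides, following the ProtParam convention.

## Phylogeny

Distances: p-distance (mismatch proportion) or Poisson-corrected
−ln(1−p), computed with pairwise deletion of gapped columns (the common
default for protein NJ; complete deletion discards too much of a
gappy HFB alignment). A taxa pair sharing no ungapped column is an error.

Tree building is Saitou–Nei neighbor joining on the Q-criterion. Ties in
Q are broken by the lowest (row, col) pair in node-creation order, so
trees are reproducible. Negative branch-length estimates are clamped to
zero. After agglomeration, internal edges of length ~0 are contracted:
NJ proper always returns a binary topology, but a zero-length internal
edge carries no grouping signal, and contracting it makes degenerate
inputs behave sensibly (an all-zero matrix yields a star tree). For an
additive matrix the recovered path lengths reproduce the input exactly;
this is property-tested against random trees of up to 12 taxa.

Bootstrap: columns are resampled with replacement, each replicate is
rebuilt with the same distance model and NJ, and each internal edge of
the original tree gets the percentage of replicates containing its
bipartition. Trees are emitted unrooted (as a trifurcating root node) in
Newick, with supports as integer internal-node labels. Alignment
construction itself is out of scope; the module consumes an existing MSA.

## Expression (2^−ΔΔCt)

Amplification efficiency is fixed at 2.0 (the pure 2^−ΔΔCt model).
ΔCt is computed per replicate against the housekeeping gene matched on
(stage, replicate); ΔΔCt subtracts the calibrator stage's replicate-mean
ΔCt, so the calibrator fold is exactly 1 and all folds are invariant to
any constant Ct offset (machine recalibration). The fold-scale SD is
propagated from the replicate ΔCt spread by the delta method,
`sd_fold = fold · ln 2 · sd(ΔCt)`; output headers state this scale.

One-way ANOVA uses the classical between/within F statistic with the
p-value from the F distribution. Degenerate inputs are pinned down:
identical data everywhere gives F = 0, p = 1; zero within-group variance
with real group differences gives F = ∞, p = 0. The stage-transition
report emits, per gene, the ratio of consecutive-stage folds, a pooled
two-sample t-test on replicate ΔCt per transition (with `*`/`**`/`ns`
stars at 0.05/0.01), and the omnibus ANOVA across all measured stages —
all pairwise information is reported rather than guessing which
comparisons a figure's brackets intended. No multiple-testing correction
is applied; the report carries the number of tests performed.

## Surface assays

Two denominator conventions, fixed by matching published reports and
stated in every output: wettability alteration is relative to the
**blank** angle (`100·|coated − blank|/blank`, direction "reduced" on a
hydrophobic surface turning wetter, "increase" on a hydrophilic surface
turning drier); rinse resilience is the post-SDS change relative to the
**coated** angle (`100·|rinsed − coated|/coated`), small values meaning
the self-assembled film survived. Percentages are rounded half-up to two
decimals; golden tests carry a ±0.02 pp tolerance to absorb differing
rounding modes in published tables.

## Synthetic data

The generator defines the study conditions the pipeline is tested under.
The shipped census plan plants 19 typical class I sequences, 3 atypical
(two 7-Cys, one 6-Cys, built by knocking skeleton cysteines out of
typical sequences) and 80 decoys, of which 20% are near-misses: 8-Cys
sequences with exactly one constrained gap one residue outside the
typical grammar, giving the classifier a sharp decision boundary to hit.
Random decoys are resampled until they classify as rejected, so planted
labels and classifier verdicts are comparable at precision = recall = 1.

Planted non-skeleton residues are drawn from a hydrophobic-biased
alphabet (no C, no W) whose weights put a planted ~110-mer's GRAVY near
the middle of the 0.270–0.951 range observed for real class I HFBs;
sequences are rejection-sampled into that GRAVY range and into the
observed pI range 3.57–8.50. All randomness flows through one seeded
generator; a fixed seed reproduces byte-identical output.

Ct tables use base Ct 26 for targets and 18 for the reference gene, four
stages × three replicates, Gaussian replicate noise (default SD 0.2
cycles, a typical technical-replicate spread); a planted log2 effect
lowers the target's stage Ct. Alignments evolve a uniform-random root
sequence along a random binary tree (branch lengths U(0.05, 0.25)) with
symmetric substitutions over the 20 letters — along a branch of length t
each site changes with probability 1 − exp(−rate·t) to a uniformly chosen
different letter.

What the generator does **not** emulate: real amino-acid composition
outside the planted constraints, signal peptides, intron structure or
codon usage, non-uniform substitution processes (no rate heterogeneity,
no exchangeability matrix, no indels), qPCR efficiency drift, or
inter-run Ct batch effects. Passing tests therefore demonstrate the
correctness of the arithmetic and the sharpness of the grammar boundary
under controlled conditions, not classifier performance on real
proteomes.

## Problem sizes used in the test suite

The suite exercises: 1,000 random sequences against the brute-force
grammar oracle; 100 random additive matrices (4–12 taxa) for NJ topology
recovery; 10,000 null replicates (3 groups × 3) for ANOVA size
calibration; 200 simulated genes for ΔΔCt parameter recovery; bootstrap
checks on 6–8 taxa × 400–500 columns with 30–60 replicates. These sizes
give stable pass/fail behavior at interactive runtimes.
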
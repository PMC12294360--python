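# Methods notes

## Scope and data model

`cubkit` consumes in-frame CDS FASTA (one record per gene, DNA or RNA,
plain or gzip) and works internally in the RNA alphabet with a fixed
alphabetical codon order, so every output table is deterministic. The
standard nuclear genetic code is the only code shipped; the
`GeneticCode` type is table-driven, so alternatives could be added, but
none are in scope. The 59-codon analysis set excludes the three stops
(UAA, UAG, UGA) and the two single-codon amino acids (AUG, UGG), which
carry no synonymous signal.

## Input filtering

The default read policy mirrors clean ORF-caller output: records whose
length is not a multiple of three, or that contain an internal stop, are
excluded and tallied in the read summary (no silent drops); a permissive
mode truncates to the last full codon instead. Codons containing
ambiguous bases are skipped at counting time and tallied per gene.
Terminal stop codons are dropped from counts by default — stop "usage" is
not synonymous choice and would otherwise perturb GC3 — with a switch to
keep them. Genes shorter than 30 codons (configurable) are excluded from
index computation, not from reading: ENC and CAI are unstable on very
short genes. Duplicate FASTA ids get an ordinal suffix (`id__2`) and a
warning, keeping downstream tables deterministic.

## Indices

**RSCU.** `X_ij / ((1/N_i) Σ_j X_ij)` per synonymous family. Families
with zero observed codons are reported as undefined (NaN), never 0, to
keep "absent" distinguishable from "avoided". Preferred codons are those
with RSCU strictly greater than 1.

**ENC.** Wright's estimator. Per family with total count n ≥ 2,
F̂ = (nΣp² − 1)/(n − 1); families with n < 2 or F̂ = 0 are left out of
their degeneracy-class average (F̂ = 0 cannot be inverted and signals an
uninformative family at small n). Classes: 2-fold (9 amino acids),
3-fold (Ile only), 4-fold (5), 6-fold (Leu, Ser, Arg — treated as
6-fold, the CodonW convention). A missing 3-fold average is imputed as
(F̄₂ + F̄₄)/2; a missing 2-, 4- or 6-fold average makes the gene's ENC
undefined (NaN, logged), not an error. The raw value is clamped at 61 —
sampling noise pushes uniform-usage genes slightly above the ceiling.
Because F̂ carries the n/(n − 1) small-sample correction, ENC is
convergent rather than exactly scale-free in the counts; tests assert
convergence, and exact scale-invariance only for RSCU and CAI.

**Expected ENC and deviation.** ENC_exp(s) = 2 + s + 29/(s² + (1 − s)²)
with s = GC3s, the third-position GC over codons of amino acids with at
least two synonyms. The per-gene deviation ratio is
(ENC_exp − ENC_obs)/ENC_exp, binned into the fixed edges
(−0.25, −0.15, −0.05, 0.05, 0.15, 0.25, 0.35) — left-closed, right-open,
last bin closed, out-of-range values counted separately. "On or near the
curve" is operationalized as the central bin, |ratio| < 0.05.

**Permutation null.** The permutation unit is the gene: each permutation
redraws the gene's codons uniformly at random within each synonymous
family conditional on the family totals (a synonymous shuffle), then
recomputes ENC and the ratio. The two-sided empirical p-value uses the
add-one convention. ENC over permutations is evaluated in a single
vectorised pass, so the default of 5000 permutations per gene is cheap
(seconds for hundreds of genes). Per-gene RNG seeds are derived from a
hash of (run seed, gene id), making the null reproducible and invariant
to gene input order. The direct per-gene ratio is always reported
alongside the null.

**CAI.** Geometric mean of w = RSCU/RSCU_max over the gene's codons,
excluding Met, Trp and stops (their weights are identically 1 and would
only dilute the signal). Reference-absent codons in an observed family
get a floor weight of 0.01, avoiding zero geometric means; a family
absent from the reference entirely gets neutral weights with a warning.
Without expression data there is no principled "highly expressed"
reference, so the default is self-referential: the 5% of genes with the
lowest defined ENC (at least 10). An external reference FASTA can be
supplied instead, and the provenance string is recorded in the weights
and the run config. CAI values are therefore comparable within a run,
not across studies using other references.

**CBI / FOP.** Over synonymous codons only: FOP = N_opt/N_tot;
CBI = (N_opt − N_rand)/(N_tot − N_rand) with N_rand the optimal count
expected under uniform usage within each family (so CBI = 0 at
uniformity, 1 when only optimal codons are used). The default optimal
set is the preferred-codon set (RSCU > 1) of the species-pooled counts;
it can be overridden.

## Diagnostics

The neutrality plot regresses GC12 on GC3 by OLS and reports Pearson r
(the standard statistic for that diagnostic); a constant predictor
yields flagged NaNs, a constant response slope 0 and r 0. The CAI–ENC
association uses Spearman rho, robust to the nonlinear ENC response.
PR2 coordinates are G3/(G3 + C3) and A3/(A3 + U3); the default site set
is all synonymous third positions, with a fourfold-only option since
classic parity analyses restrict to fourfold-degenerate families — the
choice is recorded in the run config. Quadrant I is the upper right;
points exactly on a midline go to an `on_axis` bucket and are excluded
from quadrant counts (deterministic tie-break). Species-level GC
summaries are emitted under both plausible aggregations — unweighted
gene means and pooled (concatenated-counts) values — labelled, since
published summary tables rarely say which was used.

## Synthetic data generator

Per gene: amino-acid length from a lognormal (default mean 380 aa,
sd 120, floor 30 — transcriptome-scale magnitudes); a GC3 driver d drawn
uniformly in gc3_target ± gc3_spread (default ±0.15: real
transcriptomes show wide per-gene GC3 variation, and the spread is what
gives the neutrality and ENC–GC3 plots an x-axis); amino acids i.i.d.
from `aa_frequencies` (default uniform); codons within each family with
probability ∝ base weight × exp(selection_strength · 1[codon optimal]).
Base weights split mass so that P(third base ∈ {G, C}) = d exactly in
every family — a per-base weighting would leave a small bias from the
3-codon Ile family — so at selection strength 0 the expected GC3s equals
the target exactly, and `expected_gc3s` gives the closed form (exact for
gc12_coupling 0; with coupling the per-gene amino-acid tilt makes the
expectation gene-dependent). The default optimal set has one A/U-ending
codon per family, mimicking AT-rich insect genomes.

GC12 coupling c tilts each gene's amino-acid frequencies exponentially
(1-D root solve on the tilt parameter) so its expected GC12 is
(1 − c) · baseline + c · d: c = 1 reproduces the mutation-pressure
regime (slope and r near 1), c = 0 the selection regime (r near 0).

What the generator does *not* emulate: expression levels and their
covariation with bias, isoforms and UTR contamination, amino-acid
composition differences between genes, dinucleotide or codon-pair
constraints, and assembly artifacts. Passing recovery tests therefore
shows the statistics are computed correctly and respond in the right
direction — not that real transcriptomes satisfy the generator's
assumptions.

Exponential tilting was chosen as the selection mechanism because it is
the simplest one-parameter model with a strictly monotone ENC response;
it is a stand-in for selection-mutation-drift dynamics, not a mechanistic
claim.

## Problem sizes and determinism

The test suite exercises sets of 20–120 genes for unit-level checks and
500-gene sets for parameter recovery (GC3s recovered within 3 s.e.; mean
ENC strictly decreasing over the selection-strength grid {0, 1, 2, 4};
neutrality r above 0.8 at full coupling and below 0.2 at none) — sizes
chosen so the full pipeline's behaviour is resolved while the suite
stays desk-scale. An independent brute-force oracle (its own hard-coded
code table, formulas evaluated term by term) is checked against RSCU,
ENC and CAI on 100 random count tables to 1e-9. All randomness flows
from explicit seeds; reruns with the same config produce byte-identical
tables.

## Known limitations

- CAI, CBI and FOP depend on reference/optimal-set choices; defaults are
  reproducible but not comparable to values computed against external
  reference sets (e.g. CodonW's built-in references).
- ENC is undefined for genes too short or too narrow in amino-acid usage
  to populate the degeneracy classes; such genes are excluded and
  counted, which can bias species summaries toward longer genes.
- The neutrality regression is ordinary least squares across genes;
  genes are treated as independent (no phylogenetic or gene-family
  correction).
- No correspondence analysis, tRNA adaptation index, or codon-pair
  statistics.
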
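# cubkit

Codon usage bias analysis for sets of coding sequences (CDSs), built for
comparative transcriptome studies — e.g. asking whether synonymous codon
choice in a set of insect transcriptomes is driven mainly by mutation
pressure or by translational selection.

Synonymous codons encode the same amino acid but are used unevenly.
`cubkit` quantifies that unevenness per gene and per species and runs the
standard diagnostics that separate its causes:

- **RSCU** (relative synonymous codon usage):
  RSCU<sub>ij</sub> = X<sub>ij</sub> / ((1/N<sub>i</sub>) Σ<sub>j</sub> X<sub>ij</sub>),
  the count of codon *j* of amino acid *i* relative to the family mean;
  1 = no bias, > 1 = preferred. Computed over the 59 synonymous codons
  (64 − 3 stops − Met − Trp).
- **ENC** (effective number of codons), Wright's estimator: per-family codon
  homozygosity F̂ = (nΣp² − 1)/(n − 1), averaged within degeneracy classes,
  ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆; ranges 20 (one codon per amino
  acid) to 61 (uniform usage). Compared against the mutation-only expected
  curve ENC<sub>exp</sub>(s) = 2 + s + 29/(s² + (1 − s)²) with s = GC3s,
  via the deviation ratio (ENC<sub>exp</sub> − ENC<sub>obs</sub>)/ENC<sub>exp</sub>,
  its canonical histogram bins, and an optional per-gene synonymous
  permutation null.
- **CAI** (codon adaptation index): geometric mean of relative adaptiveness
  weights w = RSCU/RSCU<sub>max</sub> from a reference gene set; **CBI** and
  **FOP** for optimal-codon usage.
- **Neutrality plot** (GC12 on GC3 regression), **PR2 plot**
  (A3/(A3+U3) vs G3/(G3+C3) at synonymous third positions), ENC strength
  classes (ENC < 35 strong, 35 ≤ ENC ≤ 50 moderate, > 50 weak), CAI–ENC
  association, preferred-codon calling (RSCU > 1), and a cross-species RSCU
  heatmap matrix.
- A **synthetic CDS generator** with controllable GC3 target, selection
  strength toward an optimal codon set, and GC12–GC3 coupling, plus a
  parameter-recovery suite — so the whole pipeline is verifiable against
  known ground truth.

## Worked example

```python
from cubkit import analyze_records
from cubkit.synthetic_data import SyntheticSpec, generate_cds_set

spec = SyntheticSpec(n_genes=500, gc3_target=0.40, selection_strength=1.0,
                     gc12_coupling=0.3, seed=42, label="ant_like")
records, truth = generate_cds_set(spec)
bundle = analyze_records(records, label="ant_like", n_perm=200, seed=42)

print(f"mean ENC:         {bundle.cub['enc_obs'].mean():.2f}")
print(f"mean CAI:         {bundle.cub['cai'].mean():.3f}")
s = bundle.strength
print(f"ENC classes:      <35: {s.n_strong}  35-50: {s.n_moderate}  >50: {s.n_weak}")
print(f"neutrality fit:   slope={bundle.neutrality.slope:.3f}  r={bundle.neutrality.r:.3f}")
print(f"preferred codons: {bundle.preferred.count} (A/U-ending: "
      f"{bundle.preferred.ending_base_tally['A/U']})")
print(f"CAI-ENC Spearman: {bundle.cai_enc_rho:.3f}")
```

prints

```
mean ENC:         45.00
mean CAI:         0.535
ENC classes:      <35: 11  35-50: 392  >50: 97
neutrality fit:   slope=0.380  r=0.737
preferred codons: 18 (A/U-ending: 18)
CAI-ENC Spearman: -0.921
```

Read: moderate selection (strength 1.0) pulls mean ENC to 45 and pushes
most genes below the mutation-only expectation; all 18 preferred codons
are the A/U-ending optimal set the generator enriched; partial GC12–GC3
coupling (0.3) yields an intermediate neutrality correlation; and CAI
rises as ENC falls (strongly negative Spearman), the signature of
translational selection. `bundle` also carries the per-gene composition
and index tables, the deviation-ratio histogram, PR2 quadrant counts, and
the permutation p-values.

## Command line

```sh
cubkit simulate --out sim.fa --n-genes 500 --gc3-target 0.4 --seed 1
cubkit species  --fasta sim.fa --out results/sim --n-perm 5000 --seed 1
cubkit compare  --fasta sp1.fa --fasta sp2.fa --out results/cmp --plots
cubkit recover  --out results/recovery --seed 1
```

Each run writes full-precision TSV tables, 2-decimal report variants,
JSON summaries, and a `config.json` that makes the run reproducible from
the output directory alone.

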
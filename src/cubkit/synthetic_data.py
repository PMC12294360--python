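"""Synthetic CDS sets with known composition and selection structure.

The generator emulates the statistical skeleton of a transcriptome-scale
codon-usage study so that every downstream statistic is testable against
ground truth:

* each gene draws an amino-acid length from a lognormal distribution
  (default mean 380 aa, matching typical transcriptome-wide means);
* each gene draws a third-position GC *driver* ``d`` around ``gc3_target``
  (the between-gene spread is what gives the neutrality and ENC–GC3 plots
  an x-axis);
* within every synonymous family the G/C-ending codons share probability
  mass ``d`` and the A/U-ending codons share ``1 − d``, so the expected
  synonymous third-position GC of a gene is exactly its driver;
* translational selection is modelled as exponential tilting: codons in
  ``optimal_set`` get an extra factor ``exp(selection_strength)`` — the
  simplest one-parameter mechanism with a monotone ENC response (a
  modelling stand-in, not a claim about any real genome);
* ``gc12_coupling`` links first/second-position composition to the same
  driver by exponentially tilting the amino-acid frequencies of each gene
  toward a target GC12 of ``(1 − c) * baseline + c * d``, so coupling 1
  reproduces the mutation-pressure regime (neutrality slope and r near 1)
  and coupling 0 the selection regime (r near 0).

Generated sequences always pass default CDS validation: length a multiple
of three, a single terminal stop, no ambiguous bases.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .cds_io import CdsRecord
from .genetic_code import GeneticCode, build_standard_code

AA_ORDER = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic CDS set (all ranges validated)."""

    n_genes: int = 500
    mean_length_aa: float = 380.0
    sd_length_aa: float = 120.0
    min_length_aa: int = 30
    aa_frequencies: dict[str, float] | None = None  # None = uniform over 20
    gc3_target: float = 0.5
    gc3_spread: float = 0.15  # half-width of the uniform per-gene driver
    selection_strength: float = 0.0
    optimal_set: tuple[str, ...] | None = None  # None = default one per family
    gc12_coupling: float = 0.0
    seed: int = 0
    label: str = "synthetic"

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.min_length_aa < 1 or self.mean_length_aa < self.min_length_aa:
            raise ValueError("length distribution inconsistent with minimum")
        if not 0.0 < self.gc3_target < 1.0:
            raise ValueError("gc3_target must lie strictly in (0, 1)")
        if not 0.0 <= self.gc3_spread < 0.5:
            raise ValueError("gc3_spread must lie in [0, 0.5)")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")
        if not 0.0 <= self.gc12_coupling <= 1.0:
            raise ValueError("gc12_coupling must lie in [0, 1]")
        if self.aa_frequencies is not None:
            if set(self.aa_frequencies) != set(AA_ORDER):
                raise ValueError("aa_frequencies must cover the 20 amino acids")
            total = sum(self.aa_frequencies.values())
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ValueError(f"aa_frequencies must sum to 1, got {total}")

    def aa_probs(self) -> np.ndarray:
        if self.aa_frequencies is None:
            return np.full(len(AA_ORDER), 1.0 / len(AA_ORDER))
        return np.array([self.aa_frequencies[a] for a in AA_ORDER])


def default_optimal_set(code: GeneticCode) -> tuple[str, ...]:
    """One optimal codon per synonymous family: the first U-ending codon,
    else the first A-ending one, else the family's first codon.  Mimics the
    A/U-ending preference typical of AT-rich insect genomes."""
    chosen = []
    for aa in sorted(code.synonymous_families):
        fam = code.synonymous_families[aa]
        for base in "UA":
            hits = [c for c in fam if c[2] == base]
            if hits:
                chosen.append(hits[0])
                break
        else:
            chosen.append(fam[0])
    return tuple(chosen)


def _codon_probs(
    code: GeneticCode, driver: float, strength: float, optimal: frozenset[str]
) -> dict[str, tuple[tuple[str, ...], np.ndarray]]:
    """Per-amino-acid codon sampling distributions for one gene.

    G/C-ending codons of a family share mass ``driver`` and A/U-ending
    codons share ``1 − driver`` before the selection tilt, so that without
    selection P(third base is G or C) equals the driver in every family.
    """
    probs: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
    for aa in AA_ORDER:
        fam = code.families[aa]
        if len(fam) == 1:
            probs[aa] = (fam, np.array([1.0]))
            continue
        gc_end = np.array([c[2] in "GC" for c in fam])
        w = np.where(
            gc_end, driver / gc_end.sum(), (1.0 - driver) / (~gc_end).sum()
        )
        w = w * np.exp(strength * np.array([c in optimal for c in fam]))
        probs[aa] = (fam, w / w.sum())
    return probs


_GC12_OF_CODON = {}  # codon -> GC fraction over positions 1 and 2


def _gc12_of(codon: str) -> float:
    if codon not in _GC12_OF_CODON:
        _GC12_OF_CODON[codon] = sum(b in "GC" for b in codon[:2]) / 2.0
    return _GC12_OF_CODON[codon]


def _aa_gc12(probs) -> np.ndarray:
    """Expected GC12 per amino acid under the gene's codon distributions."""
    return np.array(
        [
            float(np.sum(p * np.array([_gc12_of(c) for c in fam])))
            for fam, p in (probs[aa] for aa in AA_ORDER)
        ]
    )


def _tilt_aa_probs(
    base: np.ndarray, g: np.ndarray, target: float
) -> tuple[np.ndarray, float]:
    """Exponentially tilt amino-acid frequencies so the expected GC12 hits
    *target* (clamped to the achievable range); returns (probs, theta)."""

    def mean_at(theta: float) -> float:
        z = theta * g
        w = base * np.exp(z - z.max())
        w /= w.sum()
        return float(w @ g)

    lo, hi = -60.0, 60.0
    target = min(max(target, mean_at(lo)), mean_at(hi))
    if mean_at(0.0) == target:
        theta = 0.0
    else:
        theta = brentq(lambda t: mean_at(t) - target, lo, hi, xtol=1e-10)
    z = theta * g
    w = base * np.exp(z - z.max())
    return w / w.sum(), theta


def generate_cds_set(
    spec: SyntheticSpec, code: GeneticCode | None = None
) -> tuple[list[CdsRecord], dict]:
    """Generate a CDS set plus its ground-truth record (seed-deterministic)."""
    spec.validate()
    code = code or build_standard_code()
    optimal = frozenset(
        spec.optimal_set if spec.optimal_set is not None
        else default_optimal_set(code)
    )
    rng = np.random.default_rng(spec.seed)
    base_aa = spec.aa_probs()

    # lognormal parameterised by the requested mean/sd on the natural scale
    if spec.sd_length_aa > 0:
        sigma2 = math.log(1.0 + (spec.sd_length_aa / spec.mean_length_aa) ** 2)
        mu = math.log(spec.mean_length_aa) - sigma2 / 2.0
    else:
        sigma2, mu = 0.0, math.log(spec.mean_length_aa)

    # baseline expected GC12 (for the coupling target) uses the central driver
    central = _codon_probs(code, spec.gc3_target, spec.selection_strength, optimal)
    baseline_gc12 = float(base_aa @ _aa_gc12(central))

    records: list[CdsRecord] = []
    truth_genes = []
    n_digits = len(str(spec.n_genes))
    for i in range(spec.n_genes):
        length = max(
            spec.min_length_aa,
            int(round(rng.lognormal(mu, math.sqrt(sigma2)))),
        )
        d = float(
            np.clip(
                rng.uniform(
                    spec.gc3_target - spec.gc3_spread,
                    spec.gc3_target + spec.gc3_spread,
                ),
                0.02,
                0.98,
            )
        )
        probs = _codon_probs(code, d, spec.selection_strength, optimal)
        theta = 0.0
        aa_p = base_aa
        if spec.gc12_coupling > 0:
            g = _aa_gc12(probs)
            target = (1 - spec.gc12_coupling) * baseline_gc12 + spec.gc12_coupling * d
            aa_p, theta = _tilt_aa_probs(base_aa, g, target)

        aa_idx = rng.choice(len(AA_ORDER), size=length, p=aa_p)
        codons = np.empty(length, dtype=object)
        for j in np.unique(aa_idx):
            fam, p = probs[AA_ORDER[j]]
            where = np.flatnonzero(aa_idx == j)
            codons[where] = rng.choice(fam, size=where.size, p=p)
        stop = rng.choice(code.stop_codons)
        seq = "".join(codons) + stop

        gene_id = f"{spec.label}_g{i + 1:0{n_digits}d}"
        records.append(
            CdsRecord(id=gene_id, seq=seq, n_codons=length + 1, flags=set())
        )
        truth_genes.append(
            {
                "id": gene_id,
                "length_aa": int(length),
                "gc3_driver": d,
                "theta": theta,
            }
        )

    truth = {
        "spec": {
            **asdict(spec),
            "optimal_set": sorted(optimal),
            "aa_frequencies": dict(zip(AA_ORDER, base_aa.tolist())),
        },
        "baseline_gc12": baseline_gc12,
        "genes": truth_genes,
    }
    return records, truth


def expected_gc3s(spec: SyntheticSpec, code: GeneticCode | None = None) -> float:
    """Closed-form expected synonymous third-position GC of a generated set.

    Exact for ``gc12_coupling = 0`` (with coupling the per-gene amino-acid
    tilt makes the expectation gene-dependent).  The uniform driver
    distribution is integrated on a fine grid.
    """
    spec.validate()
    code = code or build_standard_code()
    optimal = frozenset(
        spec.optimal_set if spec.optimal_set is not None
        else default_optimal_set(code)
    )
    aa_p = dict(zip(AA_ORDER, spec.aa_probs()))
    syn = code.synonymous_families
    syn_mass = sum(aa_p[a] for a in syn)
    drivers = np.linspace(
        max(spec.gc3_target - spec.gc3_spread, 0.02),
        min(spec.gc3_target + spec.gc3_spread, 0.98),
        401,
    )
    vals = []
    for d in drivers:
        probs = _codon_probs(code, float(d), spec.selection_strength, optimal)
        gc = sum(
            aa_p[aa]
            * float(np.sum(p * np.array([c[2] in "GC" for c in fam])))
            for aa, (fam, p) in ((a, probs[a]) for a in syn)
        )
        vals.append(gc / syn_mass)
    return float(np.mean(vals))


def write_fasta(records: list[CdsRecord], path: str | Path, width: int = 60) -> None:
    """Write records as DNA FASTA (U -> T), fixed wrap, deterministic bytes."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            dna = rec.seq.replace("U", "T")
            for i in range(0, len(dna), width):
                fh.write(dna[i : i + width] + "\n")


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# recovery suite

def default_grid(seed: int = 0, n_genes: int = 500) -> list[SyntheticSpec]:
    """The standard recovery grid: a selection-strength ramp plus the two
    coupling extremes."""
    grid = [
        SyntheticSpec(
            n_genes=n_genes, selection_strength=s, gc12_coupling=0.3,
            seed=seed, label=f"sim_s{s:g}",
        )
        for s in (0.0, 1.0, 2.0, 4.0)
    ]
    grid += [
        SyntheticSpec(
            n_genes=n_genes, selection_strength=0.0, gc12_coupling=c,
            seed=seed + 1, label=f"sim_c{c:g}",
        )
        for c in (0.0, 1.0)
    ]
    return grid


def recovery_suite(
    spec_grid: list[SyntheticSpec], code: GeneticCode | None = None
):
    """Run the full pipeline on each spec and check parameter recovery.

    Checks: realized GC3s within 3 s.e. of the target (mutation-only rows),
    mean ENC strictly decreasing in selection strength, neutrality r
    increasing in gc12_coupling, and the preferred-codon call recovering
    the optimal set at the strongest selection.  Returns
    ``(per_spec_table, checks_table)`` as DataFrames.
    """
    import pandas as pd

    from .pipeline import analyze_records

    if not spec_grid:
        raise ValueError("spec grid is empty")
    code = code or build_standard_code()

    rows = []
    preferred_by_label = {}
    for spec in spec_grid:
        records, truth = generate_cds_set(spec, code)
        bundle = analyze_records(records, code=code, label=spec.label, n_perm=0)
        comp = bundle.composition
        enc = bundle.cub["enc_obs"].dropna()
        per_gene_gc3s = comp["gc3s"].dropna()
        preferred_by_label[spec.label] = set(bundle.preferred.codons)
        rows.append(
            {
                "label": spec.label,
                "n_genes": spec.n_genes,
                "selection_strength": spec.selection_strength,
                "gc12_coupling": spec.gc12_coupling,
                "gc3_target": spec.gc3_target,
                "realized_gc3s_mean": per_gene_gc3s.mean(),
                "realized_gc3s_se": per_gene_gc3s.std(ddof=1)
                / math.sqrt(len(per_gene_gc3s)),
                "mean_enc": enc.mean(),
                "mean_deviation_ratio": bundle.cub["deviation_ratio"].mean(),
                "neutrality_slope": bundle.neutrality.slope,
                "neutrality_r": bundle.neutrality.r,
                "n_preferred": bundle.preferred.count,
            }
        )
    per_spec = pd.DataFrame(rows).set_index("label")

    checks = []
    mut_only = per_spec[per_spec["selection_strength"] == 0]
    for label, row in mut_only.iterrows():
        err = abs(row["realized_gc3s_mean"] - row["gc3_target"])
        checks.append(
            (
                f"gc3s_recovery[{label}]",
                bool(err <= 3 * row["realized_gc3s_se"]),
                f"|{row['realized_gc3s_mean']:.4f} - {row['gc3_target']}| "
                f"vs 3*se={3 * row['realized_gc3s_se']:.4f}",
            )
        )
    ramp = per_spec.sort_values("selection_strength")
    ramp = ramp[ramp["gc12_coupling"] == ramp["gc12_coupling"].iloc[0]]
    if ramp["selection_strength"].nunique() > 1:
        enc_seq = ramp.drop_duplicates("selection_strength")["mean_enc"]
        checks.append(
            (
                "enc_monotone_in_strength",
                bool(enc_seq.is_monotonic_decreasing and enc_seq.nunique() == len(enc_seq)),
                " > ".join(f"{v:.2f}" for v in enc_seq),
            )
        )
    coupling_rows = per_spec[per_spec["selection_strength"] == 0].sort_values(
        "gc12_coupling"
    )
    if coupling_rows["gc12_coupling"].nunique() > 1:
        r_seq = coupling_rows.drop_duplicates("gc12_coupling")["neutrality_r"]
        checks.append(
            (
                "neutrality_r_increasing_in_coupling",
                bool(r_seq.is_monotonic_increasing),
                " < ".join(f"{v:.3f}" for v in r_seq),
            )
        )
    strongest = per_spec["selection_strength"].idxmax()
    if per_spec.loc[strongest, "selection_strength"] > 0:
        spec = next(s for s in spec_grid if s.label == strongest)
        opt = set(
            spec.optimal_set if spec.optimal_set is not None
            else default_optimal_set(code)
        )
        got = preferred_by_label[strongest]
        checks.append(
            (
                f"preferred_recovers_optimal[{strongest}]",
                opt <= got,
                f"{len(opt & got)}/{len(opt)} optimal codons preferred",
            )
        )
    checks_df = pd.DataFrame(checks, columns=["check", "passed", "detail"])
    return per_spec, checks_df
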
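"""Mutation-pressure versus translational-selection diagnostics.

The classic toolkit: a neutrality plot (GC12 regressed on GC3 — slope and
correlation near 1 mean directional mutation pressure moves all positions
together, near 0 means selection pins positions 1–2 while the third drifts),
the ENC–GC3 plot against the mutation-only expected curve with a binned
deviation-ratio summary and a per-gene synonymous-permutation null, ENC
strength classes, PR2 quadrant bookkeeping, the CAI–ENC association, and a
cross-species RSCU heatmap matrix.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cds_io import CodonCounts
from .composition import CompositionRecord
from .cub_indices import CUBRecord, RSCUTable, enc_batch, family_count_matrices
from .genetic_code import GeneticCode

#: Canonical deviation-ratio histogram edges; left-closed, right-open,
#: last bin closed.  Values outside go to ``n_outside``.
DEVIATION_BIN_EDGES = (-0.25, -0.15, -0.05, 0.05, 0.15, 0.25, 0.35)

#: ENC strength-class thresholds: < 35 strong, 35–50 (inclusive) moderate,
#: > 50 weak.
ENC_STRONG_BELOW = 35.0
ENC_WEAK_ABOVE = 50.0


# ---------------------------------------------------------------------------
# neutrality plot

@dataclass
class NeutralityFit:
    """OLS fit of GC12 on GC3 with the Pearson correlation."""

    slope: float
    intercept: float
    r: float
    p_value: float
    n_genes: int


def neutrality_fit(genes: list[CompositionRecord]) -> NeutralityFit:
    """Regress GC12 on GC3 across genes (ordinary least squares).

    A degenerate predictor (constant GC3) yields NaN slope and r rather
    than an error, so species-level loops never abort.
    """
    pts = [
        (g.gc3, g.gc12)
        for g in genes
        if not (math.isnan(g.gc3) or math.isnan(g.gc12))
    ]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 genes for a neutrality fit, got {len(pts)}")
    x, y = map(np.asarray, zip(*pts))
    if np.ptp(x) == 0:
        return NeutralityFit(math.nan, math.nan, math.nan, math.nan, len(pts))
    if np.ptp(y) == 0:  # flat response: no fit, no correlation
        return NeutralityFit(0.0, float(y[0]), 0.0, 1.0, len(pts))
    fit = stats.linregress(x, y)
    return NeutralityFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n_genes=len(pts),
    )


def neutrality_table(genes: list[CompositionRecord]) -> pd.DataFrame:
    """Plot-ready (gene_id, gc3, gc12) table."""
    return pd.DataFrame(
        [(g.gene_id, g.gc3, g.gc12) for g in genes],
        columns=["gene_id", "gc3", "gc12"],
    ).set_index("gene_id")


# ---------------------------------------------------------------------------
# ENC deviation from the expected curve

@dataclass
class DeviationSummary:
    """Histogram of (ENC_exp − ENC_obs)/ENC_exp over the canonical bins."""

    bin_edges: tuple[float, ...]
    frequency: list[int]
    proportion: list[float]
    n_outside: int
    n_defined: int

    def to_frame(self, decimals: int | None = 2) -> pd.DataFrame:
        labels = [
            f"[{lo:g}, {hi:g}{']' if i == len(self.frequency) - 1 else ')'}"
            for i, (lo, hi) in enumerate(
                zip(self.bin_edges[:-1], self.bin_edges[1:])
            )
        ]
        prop = (
            [round(p, decimals) for p in self.proportion]
            if decimals is not None
            else self.proportion
        )
        return pd.DataFrame(
            {"Frequency": self.frequency, "Frequencies": prop}, index=labels
        ).T


def enc_deviation_summary(genes: list[CUBRecord]) -> DeviationSummary:
    """Bin per-gene deviation ratios into the fixed histogram."""
    ratios = np.array(
        [g.deviation_ratio for g in genes if not math.isnan(g.deviation_ratio)]
    )
    edges = np.asarray(DEVIATION_BIN_EDGES)
    inside = ratios[(ratios >= edges[0]) & (ratios <= edges[-1])]
    freq, _ = np.histogram(inside, bins=edges)  # last bin closed
    n_def = len(ratios)
    prop = (freq / n_def).tolist() if n_def else [0.0] * len(freq)
    return DeviationSummary(
        bin_edges=DEVIATION_BIN_EDGES,
        frequency=freq.tolist(),
        proportion=prop,
        n_outside=int(n_def - freq.sum()),
        n_defined=n_def,
    )


# ---------------------------------------------------------------------------
# permutation null for the deviation ratio

@dataclass
class PermutationNull:
    """Synonymous-shuffle null distribution of one gene's deviation ratio."""

    gene_id: str
    observed_ratio: float
    null_ratios: np.ndarray
    p_value: float


def gene_seed(seed: int, gene_id: str) -> int:
    """Stable per-gene seed, invariant to gene input order."""
    digest = hashlib.sha256(f"{seed}:{gene_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def permutation_null(
    counts: CodonCounts,
    code: GeneticCode,
    n_perm: int = 5000,
    seed: int = 0,
) -> PermutationNull:
    """Per-gene null for the ENC deviation ratio.

    Each permutation redraws the gene's codons uniformly at random within
    each synonymous family, conditional on the family totals, then
    recomputes ENC and the ratio against the gene's own expected ENC.  The
    two-sided empirical p-value uses the add-one convention.  Deterministic
    given (seed, gene_id) and invariant to the order genes are processed in.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    from .composition import gc3s as _gc3s
    from .cub_indices import enc_expected, enc_observed

    obs_enc = enc_observed(counts, code)
    if math.isnan(obs_enc):
        raise ValueError(f"gene {counts.gene_id}: ENC undefined, cannot permute")
    exp_enc = enc_expected(_gc3s(counts, code))
    obs_ratio = (exp_enc - obs_enc) / exp_enc

    rng = np.random.default_rng(gene_seed(seed, counts.gene_id))
    null_fams = []
    for fam in family_count_matrices(counts, code):
        n = int(fam.sum())
        k = len(fam)
        null_fams.append(
            rng.multinomial(n, np.full(k, 1.0 / k), size=n_perm)
            if n
            else np.zeros((n_perm, k), dtype=np.int64)
        )
    null_enc = enc_batch(null_fams, code)
    null_ratios = (exp_enc - null_enc) / exp_enc

    finite = null_ratios[~np.isnan(null_ratios)]
    lo = (1 + np.sum(finite <= obs_ratio)) / (len(finite) + 1)
    hi = (1 + np.sum(finite >= obs_ratio)) / (len(finite) + 1)
    p = min(1.0, 2.0 * min(lo, hi))
    return PermutationNull(
        gene_id=counts.gene_id,
        observed_ratio=obs_ratio,
        null_ratios=null_ratios,
        p_value=p,
    )


# ---------------------------------------------------------------------------
# ENC strength classes

@dataclass
class EncStrengthSummary:
    """Gene counts in the strong (<35), moderate (35–50) and weak (>50)
    ENC classes."""

    n_strong: int
    n_moderate: int
    n_weak: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.n_strong, self.n_moderate, self.n_weak]],
            columns=["ENC < 35", "35 ≤ ENC ≤ 50", "50 < ENC"],
        )


def classify_enc_strength(genes: list[CUBRecord]) -> EncStrengthSummary:
    """Partition defined-ENC genes by the 35/50 thresholds (both ends of
    the moderate class inclusive)."""
    enc = np.array([g.enc_obs for g in genes if not math.isnan(g.enc_obs)])
    return EncStrengthSummary(
        n_strong=int(np.sum(enc < ENC_STRONG_BELOW)),
        n_moderate=int(
            np.sum((enc >= ENC_STRONG_BELOW) & (enc <= ENC_WEAK_ABOVE))
        ),
        n_weak=int(np.sum(enc > ENC_WEAK_ABOVE)),
    )


# ---------------------------------------------------------------------------
# PR2 quadrants

def pr2_quadrant_summary(genes: list[CompositionRecord]) -> dict[str, int]:
    """Counts of genes per PR2 quadrant.

    Quadrant I is the upper right (x > 0.5, y > 0.5), numbering
    counter-clockwise.  Points exactly on a midline go to ``on_axis`` and
    are excluded from quadrant counts; genes with undefined coordinates go
    to ``excluded``.
    """
    out = {"I": 0, "II": 0, "III": 0, "IV": 0, "on_axis": 0, "excluded": 0}
    for g in genes:
        x, y = g.pr2_x, g.pr2_y
        if math.isnan(x) or math.isnan(y):
            out["excluded"] += 1
        elif x == 0.5 or y == 0.5:
            out["on_axis"] += 1
        elif x > 0.5:
            out["I" if y > 0.5 else "IV"] += 1
        else:
            out["II" if y > 0.5 else "III"] += 1
    return out


def pr2_table(genes: list[CompositionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(g.gene_id, g.pr2_x, g.pr2_y) for g in genes],
        columns=["gene_id", "pr2_x", "pr2_y"],
    ).set_index("gene_id")


# ---------------------------------------------------------------------------
# CAI vs ENC

def cai_enc_table(genes: list[CUBRecord]) -> tuple[pd.DataFrame, float, float]:
    """Paired (cai, enc) table plus Spearman rho and its p-value.

    Rho is NaN (flagged via the return value) when either variable is
    constant.
    """
    df = pd.DataFrame(
        [
            (g.gene_id, g.cai, g.enc_obs)
            for g in genes
            if not (math.isnan(g.cai) or math.isnan(g.enc_obs))
        ],
        columns=["gene_id", "cai", "enc"],
    ).set_index("gene_id")
    if len(df) < 2 or df["cai"].nunique() == 1 or df["enc"].nunique() == 1:
        return df, math.nan, math.nan
    rho, p = stats.spearmanr(df["cai"], df["enc"])
    return df, float(rho), float(p)


# ---------------------------------------------------------------------------
# cross-species RSCU heatmap matrix

STOP_MARK = "(−)"     # stop codons
NONSYN_MARK = "(+)"        # single-codon amino acids (Met, Trp)


def rscu_heatmap_matrix(
    tables: list[RSCUTable], code: GeneticCode
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Layout RSCU for a heatmap: 16 first-two-base rows by
    (species x third base) columns.

    Returns ``(values, marks)``: values holds RSCU (NaN for stop and
    non-synonymous cells), marks holds the figure annotations — ``(−)``
    for stops and ``(+)`` for Met/Trp cells.  Row and column order is
    deterministic (alphabetical prefixes; third bases A, C, G, U; species
    in input order).
    """
    if not tables:
        raise ValueError("need at least one species RSCU table")
    prefixes = sorted({a + b for a in "ACGU" for b in "ACGU"})
    cols = pd.MultiIndex.from_tuples(
        [(t.scope_id, b) for t in tables for b in "ACGU"],
        names=["species", "third_base"],
    )
    values = pd.DataFrame(np.nan, index=prefixes, columns=cols)
    marks = pd.DataFrame("", index=prefixes, columns=cols)
    for t in tables:
        for prefix in prefixes:
            for b in "ACGU":
                codon = prefix + b
                aa = code.codon_to_aa[codon]
                if aa == "*":
                    marks.loc[prefix, (t.scope_id, b)] = STOP_MARK
                elif len(code.families[aa]) == 1:
                    marks.loc[prefix, (t.scope_id, b)] = NONSYN_MARK
                else:
                    values.loc[prefix, (t.scope_id, b)] = t.rscu[codon]
    values.index.name = "first_two_bases"
    marks.index.name = "first_two_bases"
    return values, marks
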
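"""Positional nucleotide composition and parity-rule-2 (PR2) coordinates.

GC1/GC2/GC3 are the G+C fractions at the three codon positions; GC12 is
their first/second-position mean and GC3s restricts the third position to
synonymously variable codons (amino acids with at least two codons; Met,
Trp and stops excluded), which is the quantity the expected-ENC curve is a
function of.

The PR2 plot places A3/(A3+U3) against G3/(G3+C3) over third positions of
synonymous codons: (0.5, 0.5) is intrastrand mutational parity (A = U and
G = C), and systematic displacement indicates strand- or selection-driven
asymmetry at silent sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cds_io import CodonCounts
from .genetic_code import CODONS, GeneticCode

# Boolean masks over the fixed codon order, one per position/base query.
_POS_BASE = {
    (pos, base): np.array([c[pos] == base for c in CODONS])
    for pos in range(3)
    for base in "ACGU"
}
_GC_AT_POS = {
    pos: _POS_BASE[(pos, "G")] | _POS_BASE[(pos, "C")] for pos in range(3)
}

ALL_SYNONYMOUS = "all_synonymous"
FOURFOLD_ONLY = "fourfold_only"


@dataclass
class CompositionRecord:
    """Per-gene positional GC and PR2 coordinates.

    ``pr2_x``/``pr2_y`` are NaN when a denominator is zero (the gene is
    excluded from the PR2 plot; exclusions are counted downstream).
    """

    gene_id: str
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc_all: float
    gc3s: float
    a3: int
    u3: int
    g3: int
    c3: int
    pr2_x: float
    pr2_y: float


def positional_gc(counts: CodonCounts) -> tuple[float, float, float, float, float]:
    """GC fraction at each codon position plus GC12 and overall GC."""
    if counts.total_codons < 1:
        raise ValueError(f"gene {counts.gene_id}: no codons counted")
    n = counts.total_codons
    gc1, gc2, gc3 = (
        float(counts.counts[_GC_AT_POS[pos]].sum()) / n for pos in range(3)
    )
    return gc1, gc2, gc3, (gc1 + gc2) / 2.0, (gc1 + gc2 + gc3) / 3.0


def _synonymous_mask(code: GeneticCode, fourfold_only: bool = False) -> np.ndarray:
    if fourfold_only:
        keep = {
            c
            for aa, fam in code.synonymous_families.items()
            if len(fam) == 4
            for c in fam
        }
    else:
        keep = {c for fam in code.synonymous_families.values() for c in fam}
    return np.array([c in keep for c in CODONS])


def gc3s(counts: CodonCounts, code: GeneticCode) -> float:
    """Third-position GC over synonymously variable codons only.

    Codons of single-codon amino acids (Met, Trp) and stops are excluded.
    Raises ``ValueError`` when the gene has no synonymous codons at all.
    """
    mask = _synonymous_mask(code)
    n_syn = int(counts.counts[mask].sum())
    if n_syn == 0:
        raise ValueError(
            f"gene {counts.gene_id}: GC3s undefined (no synonymous codons)"
        )
    gc = int(counts.counts[mask & _GC_AT_POS[2]].sum())
    return gc / n_syn


def third_position_base_counts(
    counts: CodonCounts, code: GeneticCode, site_set: str = ALL_SYNONYMOUS
) -> tuple[int, int, int, int]:
    """(A3, U3, G3, C3) counts over third positions of the chosen site set."""
    mask = _synonymous_mask(code, fourfold_only=site_set == FOURFOLD_ONLY)
    return tuple(
        int(counts.counts[mask & _POS_BASE[(2, b)]].sum()) for b in "AUGC"
    )


def pr2_coordinates(
    counts: CodonCounts, code: GeneticCode, site_set: str = ALL_SYNONYMOUS
) -> tuple[float, float]:
    """PR2 coordinates (G3/(G3+C3), A3/(A3+U3)); NaN on a zero denominator."""
    if site_set not in (ALL_SYNONYMOUS, FOURFOLD_ONLY):
        raise ValueError(f"unknown PR2 site set: {site_set!r}")
    a3, u3, g3, c3 = third_position_base_counts(counts, code, site_set)
    x = g3 / (g3 + c3) if g3 + c3 > 0 else math.nan
    y = a3 / (a3 + u3) if a3 + u3 > 0 else math.nan
    return x, y


def composition_record(
    counts: CodonCounts, code: GeneticCode, pr2_site_set: str = ALL_SYNONYMOUS
) -> CompositionRecord:
    """Assemble the full per-gene composition record."""
    gc1, gc2, gc3, gc12, gc_all = positional_gc(counts)
    try:
        g3s = gc3s(counts, code)
    except ValueError:
        g3s = math.nan
    a3, u3, g3, c3 = third_position_base_counts(counts, code, ALL_SYNONYMOUS)
    pr2_x, pr2_y = pr2_coordinates(counts, code, pr2_site_set)
    return CompositionRecord(
        gene_id=counts.gene_id,
        gc1=gc1, gc2=gc2, gc3=gc3, gc12=gc12, gc_all=gc_all, gc3s=g3s,
        a3=a3, u3=u3, g3=g3, c3=c3, pr2_x=pr2_x, pr2_y=pr2_y,
    )


def composition_table(records: list[CompositionRecord]) -> pd.DataFrame:
    """Per-gene composition table (full precision)."""
    df = pd.DataFrame([vars(r) for r in records]).set_index("gene_id")
    return df


def species_gc_summary(
    per_gene: pd.DataFrame, pooled: CompositionRecord, label: str
) -> pd.DataFrame:
    """Species-level GC percentages under both aggregations.

    Emits one row per aggregation: ``gene_mean`` (unweighted mean across
    genes) and ``pooled`` (computed on concatenated counts), since summary
    tables in the literature rarely state which was used.  Values are
    percentages.
    """
    cols = ["gc1", "gc2", "gc3", "gc_all"]
    rows = {
        (label, "gene_mean"): (per_gene[cols].mean() * 100).tolist(),
        (label, "pooled"): [
            getattr(pooled, c) * 100 for c in cols
        ],
    }
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["GC1%", "GC2%", "GC3%", "GCall%"]
    )
    out.index = pd.MultiIndex.from_tuples(out.index, names=["species", "aggregation"])
    return out
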
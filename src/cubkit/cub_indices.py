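"""Codon usage bias indices: RSCU, ENC (observed and expected), CAI,
CBI/FOP, and preferred-codon calls.

RSCU
    ``RSCU_ij = X_ij / ((1/N_i) * sum_j X_ij)`` — the count of codon *j* of
    amino acid *i* relative to the mean count over its synonymous family.
    1 means no bias; values above 1 mark codons used more than expected.

ENC (effective number of codons)
    Wright's estimator.  Per synonymous family with total count n >= 2 the
    codon homozygosity is ``F = (n * sum p_i^2 - 1) / (n - 1)``; family F
    values are averaged within each degeneracy class and combined as
    ``ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6``.  The statistic runs from 20
    (one codon per amino acid) to 61 (uniform synonymous usage); sampling
    noise can push the raw value above 61, so it is clamped there.  A
    missing 3-fold class (Ile is its only member) is imputed as
    ``F3 = (F2 + F4)/2``; if any other class average cannot be formed the
    gene's ENC is undefined (NaN), not an exception.

Expected ENC
    The mutation-only curve ``ENC_exp(s) = 2 + s + 29/(s^2 + (1-s)^2)``
    as a function of synonymous third-position GC (GC3s).

CAI
    Geometric mean of relative adaptiveness weights ``w = RSCU/RSCU_max``
    (derived from a reference gene set) over the gene's codons, excluding
    Met, Trp and stops.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cds_io import CodonCounts, pooled_counts
from .genetic_code import CODON_INDEX, GeneticCode

logger = logging.getLogger(__name__)

#: Smoothing floor for adaptiveness weights of codons absent from the
#: reference set; avoids zero geometric means on rare codons.
W_FLOOR = 0.01


# ---------------------------------------------------------------------------
# family indexing (cached per code object)

@dataclass(frozen=True)
class _FamilyIndex:
    aas: tuple[str, ...]
    codon_idx: tuple[np.ndarray, ...]  # indices into the 64-slot vector
    sizes: np.ndarray                  # family sizes, aligned with aas


_INDEX_CACHE: dict[int, _FamilyIndex] = {}


def _family_index(code: GeneticCode) -> _FamilyIndex:
    key = id(code)
    if key not in _INDEX_CACHE:
        fams = code.synonymous_families
        aas = tuple(sorted(fams))
        _INDEX_CACHE[key] = _FamilyIndex(
            aas=aas,
            codon_idx=tuple(
                np.array([CODON_INDEX[c] for c in fams[aa]]) for aa in aas
            ),
            sizes=np.array([len(fams[aa]) for aa in aas]),
        )
    return _INDEX_CACHE[key]


def family_count_matrices(
    counts: CodonCounts, code: GeneticCode
) -> list[np.ndarray]:
    """The gene's codon counts split by synonymous family (ENC's input)."""
    idx = _family_index(code)
    return [counts.counts[ci] for ci in idx.codon_idx]


# ---------------------------------------------------------------------------
# RSCU

@dataclass
class RSCUTable:
    """RSCU over the 59 analysis codons for one gene or one species.

    Families with zero observed codons get NaN (undefined), never 0.
    """

    scope_id: str
    rscu: dict[str, float]
    observed_families: set[str] = field(default_factory=set)


def rscu(counts: CodonCounts, code: GeneticCode) -> RSCUTable:
    """Relative synonymous codon usage of one count vector."""
    values: dict[str, float] = {}
    observed: set[str] = set()
    for aa, fam in code.synonymous_families.items():
        fam_counts = np.array([counts[c] for c in fam], dtype=float)
        total = fam_counts.sum()
        if total == 0:
            for c in fam:
                values[c] = math.nan
            continue
        observed.add(aa)
        mean = total / len(fam)
        for c, x in zip(fam, fam_counts):
            values[c] = x / mean
    ordered = {c: values[c] for c in code.analysis_codons}
    return RSCUTable(scope_id=counts.gene_id, rscu=ordered, observed_families=observed)


@dataclass
class PreferredCodons:
    """Codons with RSCU strictly above 1, with the ending-base breakdown."""

    codons: tuple[str, ...]
    count: int
    ending_base_tally: dict[str, int]


def preferred_codons(rscu_table: RSCUTable) -> PreferredCodons:
    """Codons used more than expected (RSCU > 1, strict)."""
    chosen = tuple(
        c for c, v in rscu_table.rscu.items() if not math.isnan(v) and v > 1
    )
    tally = {"A/U": 0, "G": 0, "C": 0}
    for c in chosen:
        tally["A/U" if c[2] in "AU" else c[2]] += 1
    return PreferredCodons(codons=chosen, count=len(chosen), ending_base_tally=tally)


# ---------------------------------------------------------------------------
# ENC

def enc_batch(family_counts: list[np.ndarray], code: GeneticCode) -> np.ndarray:
    """Wright's ENC for a batch of genes sharing family structure.

    ``family_counts[f]`` holds the counts of family *f*'s codons, shape
    ``(batch, size_f)`` (or ``(size_f,)`` for a single gene).  Families with
    total count < 2 or homozygosity exactly 0 are left out of their class
    average.  Returns one ENC per batch row, NaN where undefined.
    """
    idx = _family_index(code)
    mats = [np.atleast_2d(np.asarray(m, dtype=float)) for m in family_counts]
    batch = mats[0].shape[0]

    f_hat = np.full((batch, len(idx.aas)), np.nan)
    for f, mat in enumerate(mats):
        n = mat.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            sum_p2 = (mat**2).sum(axis=1) / n**2
            fh = (n * sum_p2 - 1.0) / (n - 1.0)
        fh = np.where((n >= 2) & (fh > 0), fh, np.nan)
        f_hat[:, f] = fh

    class_means: dict[int, np.ndarray] = {}
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        for k in (2, 3, 4, 6):
            cols = np.flatnonzero(idx.sizes == k)
            class_means[k] = (
                np.nanmean(f_hat[:, cols], axis=1) if cols.size else
                np.full(batch, np.nan)
            )
    f2, f3, f4, f6 = (class_means[k] for k in (2, 3, 4, 6))
    f3 = np.where(np.isnan(f3), (f2 + f4) / 2.0, f3)  # Ile-only class
    with np.errstate(divide="ignore", invalid="ignore"):
        enc = 2.0 + 9.0 / f2 + 1.0 / f3 + 5.0 / f4 + 3.0 / f6
    return np.minimum(enc, 61.0)


def enc_observed(counts: CodonCounts, code: GeneticCode) -> float:
    """Wright's effective number of codons for one gene (NaN if undefined)."""
    if counts.total_codons == 0:
        return math.nan
    value = float(enc_batch(family_count_matrices(counts, code), code)[0])
    if math.isnan(value):
        logger.debug("gene %s: ENC undefined (missing degeneracy class)",
                     counts.gene_id)
    return value


def enc_expected(gc3s: float) -> float:
    """Mutation-only expected ENC at synonymous third-position GC ``gc3s``."""
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError(f"GC3s must be in [0, 1], got {gc3s}")
    s = gc3s
    return 2.0 + s + 29.0 / (s**2 + (1.0 - s) ** 2)


# ---------------------------------------------------------------------------
# CAI

@dataclass
class CaiWeights:
    """Relative adaptiveness weights over the 61 sense codons."""

    w: dict[str, float]
    reference_description: str


def cai_weights(
    reference: list[CodonCounts],
    code: GeneticCode,
    description: str = "user-supplied reference set",
) -> CaiWeights:
    """Adaptiveness weights ``w = RSCU / max family RSCU`` from a pooled
    reference gene set.

    Reference-absent codons in an observed family get the smoothing floor
    (:data:`W_FLOOR`); a family absent from the reference entirely gets
    neutral weights 1 with a warning.
    """
    if not reference:
        raise ValueError("reference gene set is empty")
    pooled = pooled_counts(reference, "reference")
    table = rscu(pooled, code)
    w: dict[str, float] = {c: 1.0 for c in code.sense_codons}
    for aa, fam in code.synonymous_families.items():
        if aa not in table.observed_families:
            logger.warning(
                "CAI reference has no codons for %s; weights set to 1", aa
            )
            continue
        fam_rscu = np.array([table.rscu[c] for c in fam])
        top = fam_rscu.max()
        for c, r in zip(fam, fam_rscu):
            w[c] = max(r / top, W_FLOOR)
    return CaiWeights(w=w, reference_description=description)


def cai(counts: CodonCounts, weights: CaiWeights) -> float:
    """Codon adaptation index: geometric mean of weights over the gene's
    synonymous codons (Met, Trp and stops excluded).  NaN when the gene has
    no eligible codons.
    """
    log_sum = 0.0
    n = 0
    for codon, w in weights.w.items():
        if codon in ("AUG", "UGG"):
            continue
        x = counts[codon]
        if x:
            log_sum += x * math.log(w)
            n += x
    if n == 0:
        return math.nan
    return math.exp(log_sum / n)


def select_reference_by_enc(
    counts_list: list[CodonCounts],
    code: GeneticCode,
    fraction: float = 0.05,
    min_genes: int = 10,
) -> tuple[list[CodonCounts], str]:
    """Pick the most biased genes (lowest ENC) as a CAI reference set.

    A self-referential stand-in for a highly-expressed gene set when no
    expression data is available: the ``fraction`` of genes with the lowest
    defined ENC (at least ``min_genes``, capped at the gene count).
    """
    enc = [(enc_observed(c, code), i) for i, c in enumerate(counts_list)]
    defined = sorted((e, i) for e, i in enc if not math.isnan(e))
    if not defined:
        raise ValueError("no gene has a defined ENC; cannot build reference")
    k = min(len(defined), max(min_genes, math.ceil(fraction * len(defined))))
    chosen = [counts_list[i] for _, i in defined[:k]]
    desc = (
        f"self-referential: {k} genes with lowest ENC "
        f"(bottom {fraction:.0%} of {len(defined)} genes with defined ENC)"
    )
    return chosen, desc


# ---------------------------------------------------------------------------
# CBI / FOP

def cbi_fop(
    counts: CodonCounts, optimal: set[str], code: GeneticCode
) -> tuple[float, float]:
    """Codon bias index and frequency of optimal codons.

    Over synonymous codons only: ``FOP = N_opt / N_tot`` and
    ``CBI = (N_opt - N_rand) / (N_tot - N_rand)`` where ``N_rand`` is the
    optimal-codon count expected under uniform usage within each family.
    """
    optimal = {c.upper().replace("T", "U") for c in optimal}
    if not optimal:
        raise ValueError("optimal codon set is empty")
    bad = [c for c in optimal if code.codon_to_aa.get(c, "*") == "*"]
    if bad:
        raise ValueError(f"optimal set contains non-sense codons: {bad}")
    n_tot = n_opt = 0
    n_rand = 0.0
    for aa, fam in code.synonymous_families.items():
        fam_counts = [counts[c] for c in fam]
        fam_total = sum(fam_counts)
        n_tot += fam_total
        k_opt = sum(1 for c in fam if c in optimal)
        n_rand += fam_total * k_opt / len(fam)
        n_opt += sum(x for c, x in zip(fam, fam_counts) if c in optimal)
    if n_tot == 0:
        return math.nan, math.nan
    fop = n_opt / n_tot
    cbi = math.nan if n_tot == n_rand else (n_opt - n_rand) / (n_tot - n_rand)
    return cbi, fop


# ---------------------------------------------------------------------------
# per-gene record

@dataclass
class CUBRecord:
    """All per-gene codon-usage-bias indices in one row."""

    gene_id: str
    l_aa: int
    enc_obs: float
    enc_exp: float
    deviation_ratio: float
    cai: float
    cbi: float
    fop: float


def cub_record(
    counts: CodonCounts,
    code: GeneticCode,
    weights: CaiWeights,
    optimal: set[str],
    gc3s_value: float,
) -> CUBRecord:
    """Assemble the per-gene index record.

    ``deviation_ratio = (ENC_exp - ENC_obs) / ENC_exp``: positive when the
    gene is more biased than the mutation-only curve predicts.
    """
    obs = enc_observed(counts, code)
    exp = enc_expected(gc3s_value) if not math.isnan(gc3s_value) else math.nan
    ratio = (
        (exp - obs) / exp
        if not (math.isnan(obs) or math.isnan(exp))
        else math.nan
    )
    cbi_v, fop_v = cbi_fop(counts, optimal, code)
    l_aa = sum(counts[c] for c in code.sense_codons)
    return CUBRecord(
        gene_id=counts.gene_id,
        l_aa=l_aa,
        enc_obs=obs,
        enc_exp=exp,
        deviation_ratio=ratio,
        cai=cai(counts, weights),
        cbi=cbi_v,
        fop=fop_v,
    )
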
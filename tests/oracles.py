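"""Independent brute-force oracles for the codon-usage statistics.

Everything here is computed term by term from plainly written formulas on
dict-based count tables, with its own hard-coded genetic code table, so
these functions share no code path with the package implementation.
"""

from __future__ import annotations

import math

# Hard-coded standard nuclear code, written out family by family.
ORACLE_FAMILIES: dict[str, list[str]] = {
    "F": ["UUU", "UUC"],
    "L": ["UUA", "UUG", "CUU", "CUC", "CUA", "CUG"],
    "I": ["AUU", "AUC", "AUA"],
    "M": ["AUG"],
    "V": ["GUU", "GUC", "GUA", "GUG"],
    "S": ["UCU", "UCC", "UCA", "UCG", "AGU", "AGC"],
    "P": ["CCU", "CCC", "CCA", "CCG"],
    "T": ["ACU", "ACC", "ACA", "ACG"],
    "A": ["GCU", "GCC", "GCA", "GCG"],
    "Y": ["UAU", "UAC"],
    "*": ["UAA", "UAG", "UGA"],
    "H": ["CAU", "CAC"],
    "Q": ["CAA", "CAG"],
    "N": ["AAU", "AAC"],
    "K": ["AAA", "AAG"],
    "D": ["GAU", "GAC"],
    "E": ["GAA", "GAG"],
    "C": ["UGU", "UGC"],
    "W": ["UGG"],
    "R": ["CGU", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "G": ["GGU", "GGC", "GGA", "GGG"],
}

ORACLE_AA_OF: dict[str, str] = {
    c: aa for aa, fam in ORACLE_FAMILIES.items() for c in fam
}

SYNONYMOUS_FAMILIES = {
    aa: fam
    for aa, fam in ORACLE_FAMILIES.items()
    if aa != "*" and len(fam) >= 2
}


def oracle_rscu(counts: dict[str, int]) -> dict[str, float]:
    """RSCU_ij = X_ij / ((1/N_i) * sum_j X_ij), NaN for unobserved families."""
    out: dict[str, float] = {}
    for aa, fam in SYNONYMOUS_FAMILIES.items():
        xs = [counts.get(c, 0) for c in fam]
        total = sum(xs)
        for c, x in zip(fam, xs):
            out[c] = math.nan if total == 0 else x / (total / len(fam))
    return out


def oracle_enc(counts: dict[str, int]) -> float:
    """Wright's ENC evaluated family by family, class by class."""
    f_by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, fam in SYNONYMOUS_FAMILIES.items():
        xs = [counts.get(c, 0) for c in fam]
        n = sum(xs)
        if n < 2:
            continue
        sum_p2 = sum((x / n) ** 2 for x in xs)
        f_hat = (n * sum_p2 - 1.0) / (n - 1.0)
        if f_hat > 0:
            f_by_class[len(fam)].append(f_hat)
    means = {
        k: (sum(v) / len(v) if v else math.nan) for k, v in f_by_class.items()
    }
    if math.isnan(means[3]):
        means[3] = (means[2] + means[4]) / 2.0
    if any(math.isnan(means[k]) for k in (2, 3, 4, 6)):
        return math.nan
    enc = 2.0 + 9.0 / means[2] + 1.0 / means[3] + 5.0 / means[4] + 3.0 / means[6]
    return min(enc, 61.0)


def oracle_cai_weights(counts: dict[str, int], floor: float = 0.01) -> dict[str, float]:
    """w = RSCU / max family RSCU, floored, neutral for absent families."""
    table = oracle_rscu(counts)
    w = {c: 1.0 for c in ORACLE_AA_OF if ORACLE_AA_OF[c] != "*"}
    for aa, fam in SYNONYMOUS_FAMILIES.items():
        vals = [table[c] for c in fam]
        if math.isnan(vals[0]):
            continue
        top = max(vals)
        for c, v in zip(fam, vals):
            w[c] = max(v / top, floor)
    return w


def oracle_cai(counts: dict[str, int], w: dict[str, float]) -> float:
    """Geometric mean of weights over codons, excluding Met/Trp/stops."""
    log_sum, n = 0.0, 0
    for codon, x in counts.items():
        if x == 0 or codon in ("AUG", "UGG") or ORACLE_AA_OF[codon] == "*":
            continue
        log_sum += x * math.log(w[codon])
        n += x
    return math.nan if n == 0 else math.exp(log_sum / n)
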
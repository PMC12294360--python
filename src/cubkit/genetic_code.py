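"""Standard nuclear genetic code: synonymous families, degeneracy classes,
and the 59-codon analysis set.

All codons are handled in the RNA alphabet (``U``, not ``T``); DNA input is
transcribed at read time by :mod:`cubkit.cds_io`.  Codon order is fixed
(alphabetical over A, C, G, U) so every downstream table is deterministic.

The 59-codon *analysis set* used for RSCU tables and preferred-codon calls
is the 64 codons minus the three stop codons (UAA, UAG, UGA) and the two
amino acids with a single codon (Met = AUG, Trp = UGG), which carry no
synonymous choice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Data import CodonTable

STOP_SYMBOL = "*"

#: The 64 RNA codons in fixed alphabetical order (A < C < G < U).
CODONS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product("ACGU", repeat=3)
)

#: Codon string -> position in :data:`CODONS`.
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code with its synonymous structure.

    Attributes
    ----------
    codon_to_aa
        Map of all 64 codons to a one-letter amino-acid symbol, with stop
        codons mapped to ``"*"``.
    families
        Amino-acid symbol -> alphabetically ordered tuple of its codons.
        Includes the ``"*"`` (stop) family.
    degeneracy_classes
        Family size (1, 2, 3, 4 or 6) -> ordered tuple of the sense amino
        acids whose family has that size.  Stops are excluded.
    analysis_codons
        The ordered synonymous codon set retained for RSCU output.
    """

    codon_to_aa: dict[str, str]
    families: dict[str, tuple[str, ...]]
    degeneracy_classes: dict[int, tuple[str, ...]]
    analysis_codons: tuple[str, ...]
    stop_codons: tuple[str, ...] = field(default=("UAA", "UAG", "UGA"))

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(f"expected 64 codons, got {len(self.codon_to_aa)}")
        covered = sorted(c for fam in self.families.values() for c in fam)
        if covered != sorted(CODONS):
            raise ValueError("families do not partition the 64 codons")

    # -- lookups ---------------------------------------------------------

    def aa_of(self, codon: str) -> str:
        codon = _normalize(codon)
        return self.codon_to_aa[codon]

    def family_of(self, codon: str) -> tuple[str, ...]:
        """The full ordered synonymous family containing *codon*."""
        return self.families[self.aa_of(codon)]

    def family_size(self, codon: str) -> int:
        return len(self.family_of(codon))

    def is_stop(self, codon: str) -> bool:
        return self.aa_of(codon) == STOP_SYMBOL

    def is_synonymous(self, codon: str) -> bool:
        """True for sense codons whose amino acid has >= 2 codons."""
        aa = self.aa_of(codon)
        return aa != STOP_SYMBOL and len(self.families[aa]) >= 2

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if not self.is_stop(c))

    @property
    def synonymous_families(self) -> dict[str, tuple[str, ...]]:
        """Sense families with >= 2 codons (the families ENC/GC3s use)."""
        return {
            aa: fam
            for aa, fam in self.families.items()
            if aa != STOP_SYMBOL and len(fam) >= 2
        }


def _normalize(codon: str) -> str:
    token = codon.strip().upper().replace("T", "U")
    if len(token) != 3 or any(b not in "ACGU" for b in token):
        raise ValueError(f"invalid codon: {codon!r}")
    return token


def build_standard_code() -> GeneticCode:
    """Build the validated standard nuclear genetic code.

    The codon table itself comes from Biopython's standard RNA table; this
    function derives the synonymous families, degeneracy classes and the
    59-codon analysis set from it.
    """
    table = CodonTable.unambiguous_rna_by_id[1]
    codon_to_aa = {c: STOP_SYMBOL for c in table.stop_codons}
    codon_to_aa.update(table.forward_table)
    codon_to_aa = {c: codon_to_aa[c] for c in CODONS}

    families: dict[str, list[str]] = {}
    for codon in CODONS:  # alphabetical order within each family
        families.setdefault(codon_to_aa[codon], []).append(codon)
    families_t = {aa: tuple(cs) for aa, cs in families.items()}

    degeneracy: dict[int, list[str]] = {}
    for aa in sorted(families_t):
        if aa == STOP_SYMBOL:
            continue
        degeneracy.setdefault(len(families_t[aa]), []).append(aa)
    degeneracy_t = {k: tuple(v) for k, v in sorted(degeneracy.items())}

    analysis = tuple(
        c
        for c in CODONS
        if codon_to_aa[c] != STOP_SYMBOL and len(families_t[codon_to_aa[c]]) >= 2
    )
    code = GeneticCode(
        codon_to_aa=codon_to_aa,
        families=families_t,
        degeneracy_classes=degeneracy_t,
        analysis_codons=analysis,
        stop_codons=tuple(sorted(table.stop_codons)),
    )
    assert len(code.analysis_codons) == 59
    return code


def synonymous_family(code: GeneticCode, codon: str) -> list[str]:
    """Return the ordered synonymous family containing *codon* (inclusive).

    Stop codons return the stop set.  Raises ``ValueError`` naming the
    offending token for anything that is not one of the 64 codons.
    """
    return list(code.families[code.aa_of(codon)])
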
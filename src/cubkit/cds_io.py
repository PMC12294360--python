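"""Reading and validating CDS FASTA files, and per-gene codon counting.

Input is one FASTA record per coding sequence, expected in frame with a
length that is a multiple of three.  Sequences are upper-cased and
transcribed to the RNA alphabet on read.  The default filter policy mirrors
clean ORF-caller output: records with a non-multiple-of-3 length or an
internal stop codon are excluded (and tallied in the read summary); a
permissive mode truncates trailing partial codons instead.  Codons with
ambiguous bases are never fatal — they are skipped at counting time and
tallied per gene.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .genetic_code import CODON_INDEX, CODONS, GeneticCode

logger = logging.getLogger(__name__)

PARTIAL_LENGTH = "PARTIAL_LENGTH"
INTERNAL_STOP = "INTERNAL_STOP"
AMBIGUOUS_BASE = "AMBIGUOUS_BASE"

_STOPS = frozenset({"UAA", "UAG", "UGA"})


@dataclass(frozen=True)
class FilterPolicy:
    """How to treat records that fail validation.

    on_partial_length: ``"drop"`` (default) excludes records whose length is
    not a multiple of 3; ``"truncate"`` keeps them, trimmed to the last full
    codon. drop_internal_stop: exclude records with a stop codon before the
    final position. min_codons: minimum codon count to keep a record (0 at
    read time; index pipelines typically require 30).
    """

    on_partial_length: str = "drop"
    drop_internal_stop: bool = True
    min_codons: int = 0

    def __post_init__(self) -> None:
        if self.on_partial_length not in ("drop", "truncate"):
            raise ValueError(
                f"on_partial_length must be 'drop' or 'truncate', "
                f"got {self.on_partial_length!r}"
            )


DEFAULT_POLICY = FilterPolicy()


@dataclass
class CdsRecord:
    """One validated coding sequence (RNA alphabet)."""

    id: str
    seq: str
    n_codons: int
    flags: set[str] = field(default_factory=set)


@dataclass
class CodonCounts:
    """Per-gene 64-slot codon count vector, indexed by ``genetic_code.CODONS``."""

    gene_id: str
    counts: np.ndarray
    total_codons: int
    n_skipped: int = 0

    def __getitem__(self, codon: str) -> int:
        return int(self.counts[CODON_INDEX[codon.upper().replace("T", "U")]])

    def as_dict(self, nonzero_only: bool = True) -> dict[str, int]:
        return {
            c: int(n)
            for c, n in zip(CODONS, self.counts)
            if n > 0 or not nonzero_only
        }


@dataclass
class ReadResult:
    """Records surviving the filter policy plus an exclusion summary."""

    records: list[CdsRecord]
    summary: dict[str, int]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _codons_of(seq: str) -> list[str]:
    return [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]


def read_cds_fasta(
    path: str | Path, policy: FilterPolicy = DEFAULT_POLICY
) -> ReadResult:
    """Read a CDS FASTA (plain or gzip) and validate each record.

    Returns records in file order.  Sequences are upper-cased and T->U
    transcribed.  Duplicate ids get an ordinal suffix (``id__2``) with a
    warning.  Raises ``ValueError`` if no record survives the policy.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    summary = {
        "n_total": 0,
        "n_kept": 0,
        PARTIAL_LENGTH: 0,
        INTERNAL_STOP: 0,
        AMBIGUOUS_BASE: 0,
        "n_too_short": 0,
        "n_duplicate_ids": 0,
    }
    records: list[CdsRecord] = []
    seen: dict[str, int] = {}
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            summary["n_total"] += 1
            seq = str(rec.seq).upper().replace("T", "U")
            flags: set[str] = set()

            if len(seq) % 3 != 0:
                flags.add(PARTIAL_LENGTH)
                summary[PARTIAL_LENGTH] += 1
                if policy.on_partial_length == "drop":
                    continue
                seq = seq[: len(seq) - len(seq) % 3]

            codons = _codons_of(seq)
            if any(c in _STOPS for c in codons[:-1]):
                flags.add(INTERNAL_STOP)
                summary[INTERNAL_STOP] += 1
                if policy.drop_internal_stop:
                    continue
            if any(b not in "ACGU" for b in seq):
                flags.add(AMBIGUOUS_BASE)
                summary[AMBIGUOUS_BASE] += 1

            if len(codons) < policy.min_codons:
                summary["n_too_short"] += 1
                continue

            gene_id = rec.id
            if gene_id in seen:
                seen[gene_id] += 1
                summary["n_duplicate_ids"] += 1
                new_id = f"{gene_id}__{seen[gene_id]}"
                logger.warning("duplicate FASTA id %r renamed to %r", gene_id, new_id)
                gene_id = new_id
            else:
                seen[gene_id] = 1
            if not gene_id:
                raise ValueError("empty FASTA id encountered")

            records.append(
                CdsRecord(id=gene_id, seq=seq, n_codons=len(codons), flags=flags)
            )
            summary["n_kept"] += 1

    if not records:
        raise ValueError(f"no CDS records in {path} survived the filter policy")
    logger.info(
        "read %d/%d CDS records from %s (%s)",
        summary["n_kept"], summary["n_total"], path,
        ", ".join(f"{k}={v}" for k, v in summary.items() if k.startswith(("PARTIAL", "INTERNAL", "AMBIG", "n_too", "n_dup")) and v),
    )
    return ReadResult(records=records, summary=summary)


def count_codons(
    record: CdsRecord,
    code: GeneticCode,
    drop_terminal_stop: bool = True,
) -> CodonCounts:
    """Count consecutive non-overlapping codons of a validated record.

    If ``drop_terminal_stop`` and the final codon is a stop, it is omitted.
    Codons containing a non-ACGU base are skipped and tallied in
    ``n_skipped`` rather than raising.
    """
    codons = _codons_of(record.seq)
    if drop_terminal_stop and codons and code.codon_to_aa.get(codons[-1]) == "*":
        codons = codons[:-1]
    counts = np.zeros(64, dtype=np.int64)
    skipped = 0
    for codon in codons:
        idx = CODON_INDEX.get(codon)
        if idx is None:
            skipped += 1
        else:
            counts[idx] += 1
    return CodonCounts(
        gene_id=record.id,
        counts=counts,
        total_codons=int(counts.sum()),
        n_skipped=skipped,
    )


def pooled_counts(counts_list: list[CodonCounts], label: str) -> CodonCounts:
    """Sum codon counts across genes (species-level pooling)."""
    if not counts_list:
        raise ValueError("cannot pool an empty list of codon counts")
    total = np.sum([c.counts for c in counts_list], axis=0)
    return CodonCounts(
        gene_id=label,
        counts=total.astype(np.int64),
        total_codons=int(total.sum()),
        n_skipped=sum(c.n_skipped for c in counts_list),
    )


def counts_table(counts_list: list[CodonCounts]):
    """Per-gene codon count table: gene_id, 64 codon columns, total_codons."""
    import pandas as pd

    rows = {c.gene_id: c.counts for c in counts_list}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(CODONS))
    df.index.name = "gene_id"
    df["total_codons"] = [c.total_codons for c in counts_list]
    return df
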
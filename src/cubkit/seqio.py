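"""CDS input, validation/filtering, codon counting and gene-set grouping.

The pipeline starts from a multi-FASTA of coding sequences. Sequences are
upper-cased and RNA input (U) is mapped to the internal DNA alphabet on
read. A :class:`FilterPolicy` rejects sequences for which in-frame codon
counting would be ill-defined (length not divisible by three, ambiguous
bases, internal stop codons); rejections are logged, never raised.

Counting produces a :class:`CodonCountTable` — a genes x 64 integer matrix
in the fixed codon order of :data:`cubkit.genetic_code.CODONS` — which is
the single source for every downstream statistic.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genetic_code import CODON_INDEX, CODONS, GeneticCode, STANDARD_CODE

_VALID_BASES = frozenset("ACGTN")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input."""


@dataclass(frozen=True)
class GeneRecord:
    """One CDS: identifier, free-text description, DNA sequence."""

    gene_id: str
    description: str
    sequence: str


@dataclass(frozen=True)
class FilterPolicy:
    """Which validation rules to apply before codon counting.

    All rules default to the minimal set under which in-frame codon
    counting is well defined.
    """

    require_multiple_of_three: bool = True
    drop_ambiguous: bool = True       # any base outside A/C/G/T
    drop_internal_stop: bool = True
    min_length_codons: int = 0


@dataclass
class FilterLog:
    """Per-reason rejection counts from :func:`validate_and_filter`."""

    n_input: int = 0
    n_retained: int = 0
    reasons: Counter = field(default_factory=Counter)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"reason": r, "count": c} for r, c in sorted(self.reasons.items())]
        rows.append({"reason": "retained", "count": self.n_retained})
        return pd.DataFrame(rows, columns=["reason", "count"])


@dataclass(frozen=True)
class GeneSetLabel:
    """A named gene set (species / subgenome analogue)."""

    label: str
    member_ids: frozenset[str]


@dataclass(frozen=True)
class CodonCountTable:
    """Per-gene and pooled counts of the 64 codons.

    ``per_gene`` is an integer DataFrame with one row per gene (index =
    gene_id, insertion order preserved) and the 64 codons as columns.
    """

    per_gene: pd.DataFrame

    def __post_init__(self):
        if tuple(self.per_gene.columns) != CODONS:
            raise ValueError("count table columns must be the 64 codons in standard order")

    @property
    def pooled(self) -> pd.Series:
        return self.per_gene.sum(axis=0)

    @property
    def n_genes(self) -> int:
        return len(self.per_gene)

    @property
    def n_codons(self) -> int:
        return int(self.per_gene.to_numpy().sum())

    @property
    def gene_ids(self) -> list[str]:
        return list(self.per_gene.index)

    def subset(self, gene_ids: Iterable[str]) -> "CodonCountTable":
        ids = [g for g in self.per_gene.index if g in set(gene_ids)]
        return CodonCountTable(self.per_gene.loc[ids])


def read_cds_fasta(path: str | Path) -> list[GeneRecord]:
    """Read a CDS FASTA into :class:`GeneRecord` objects, order preserved.

    Sequences are upper-cased and U is mapped to T. A file whose first
    non-blank content is not a ``>`` header is rejected with the offending
    line number.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before first FASTA header"
                )
            break
    records = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper().replace("U", "T")
            records.append(GeneRecord(rec.id, rec.description, seq))
    return records


def write_cds_fasta(records: Sequence[GeneRecord], path: str | Path, width: int = 70) -> None:
    """Write records as wrapped FASTA (inverse of :func:`read_cds_fasta`)."""
    with open(path, "w") as out:
        for rec in records:
            header = rec.description if rec.description else rec.gene_id
            out.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


def _internal_stop(seq: str, code: GeneticCode) -> bool:
    # terminal stop is legitimate; any earlier in-frame stop is not
    for i in range(0, len(seq) - 3, 3):
        if seq[i : i + 3] in code.stop_codons:
            return True
    return False


def validate_and_filter(
    records: Sequence[GeneRecord],
    policy: FilterPolicy = FilterPolicy(),
    code: GeneticCode = STANDARD_CODE,
) -> tuple[list[GeneRecord], FilterLog]:
    """Apply ``policy`` to ``records``; return retained records and a log.

    Rules are checked in a fixed order and only the first failing reason is
    logged per sequence.
    """
    log = FilterLog(n_input=len(records))
    retained: list[GeneRecord] = []
    for rec in records:
        seq = rec.sequence
        if policy.require_multiple_of_three and len(seq) % 3 != 0:
            log.reasons["length not divisible by 3"] += 1
            continue
        if policy.min_length_codons and len(seq) < 3 * policy.min_length_codons:
            log.reasons[f"shorter than {policy.min_length_codons} codons"] += 1
            continue
        if policy.drop_ambiguous and (set(seq) - set("ACGT")):
            log.reasons["ambiguous or invalid base"] += 1
            continue
        if policy.drop_internal_stop and len(seq) % 3 == 0 and _internal_stop(seq, code):
            log.reasons["internal stop"] += 1
            continue
        retained.append(rec)
    log.n_retained = len(retained)
    return retained, log


def count_codons(
    records: Sequence[GeneRecord],
    code: GeneticCode = STANDARD_CODE,
    drop_terminal_stop: bool = True,
) -> CodonCountTable:
    """Tally in-frame codons per gene into a :class:`CodonCountTable`.

    A trailing stop codon is excluded when ``drop_terminal_stop`` is set
    (a stop can occur only once per CDS, so it carries no usage signal).
    Internal stop codons and Met/Trp are counted here; each downstream
    index excludes what its own definition requires.
    """
    mat = np.zeros((len(records), 64), dtype=np.int64)
    ids = []
    for row, rec in enumerate(records):
        seq = rec.sequence
        if len(seq) % 3 != 0:
            raise ValueError(f"{rec.gene_id}: length {len(seq)} not divisible by 3")
        end = len(seq)
        if drop_terminal_stop and end >= 3 and seq[end - 3 : end] in code.stop_codons:
            end -= 3
        for i in range(0, end, 3):
            idx = CODON_INDEX.get(seq[i : i + 3])
            if idx is not None:  # codons with N are simply not counted
                mat[row, idx] += 1
        ids.append(rec.gene_id)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate gene ids in record set")
    return CodonCountTable(pd.DataFrame(mat, index=ids, columns=list(CODONS)))


def split_by_pattern(
    records: Sequence[GeneRecord],
    rules: Mapping[str, str] | Sequence[tuple[str, str]],
    unassigned_label: str = "unassigned",
) -> list[GeneSetLabel]:
    """Group genes into labelled sets by regex search on gene ids.

    Each record joins every label whose pattern matches its id (a gene may
    belong to several sets); records matching no rule are collected under
    ``unassigned_label``. Mirrors subgenome splits driven by id prefixes
    such as ``Gh_A01...`` vs ``Gh_D01...``.
    """
    if not isinstance(rules, Mapping):
        labels = [lab for lab, _ in rules]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate labels in grouping rules")
        rules = dict(rules)
    if unassigned_label in rules:
        raise ValueError(f"label {unassigned_label!r} is reserved")
    compiled = {lab: re.compile(pat) for lab, pat in rules.items()}
    members: dict[str, set[str]] = {lab: set() for lab in rules}
    unmatched: set[str] = set()
    for rec in records:
        hit = False
        for lab, rx in compiled.items():
            if rx.search(rec.gene_id):
                members[lab].add(rec.gene_id)
                hit = True
        if not hit:
            unmatched.add(rec.gene_id)
    out = [GeneSetLabel(lab, frozenset(ids)) for lab, ids in members.items()]
    out.append(GeneSetLabel(unassigned_label, frozenset(unmatched)))
    return out
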
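"""Base-composition indices of codon usage.

Two distinct conventions coexist and are never conflated:

* ``GC``, ``GC1``, ``GC2``, ``GC3``, ``GC12`` are plain nucleotide
  fractions over **all sense codons** (Met and Trp included, stops
  excluded); ``GC12 = (GC1 + GC2) / 2``.
* ``A3s/T3s/G3s/C3s`` and ``GC3s`` are **synonymous** third-position
  frequencies over codons of multi-codon amino acids only. For a base X,
  the denominator of ``X3s`` is restricted to synonymous codons whose
  family offers at least one X-ending synonym (the CodonW
  "family potential" convention) — which is why the four X3s values of a
  genome typically sum to more than 1. ``GC3s`` divides by all synonymous
  codons, so ``GC3s <= G3s + C3s``.

Undefined values (empty denominators) are carried as NaN throughout and
rendered as ``NA`` in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .genetic_code import CODONS, GeneticCode, STANDARD_CODE
from .seqio import CodonCountTable

INDEX_NAMES = ("T3s", "A3s", "G3s", "C3s", "GC3s", "GC", "GC1", "GC2", "GC3", "GC12")


@dataclass(frozen=True)
class CompositionProfile:
    """The composition index vector for one gene or one pooled gene set."""

    T3s: float
    A3s: float
    G3s: float
    C3s: float
    GC3s: float
    GC: float
    GC1: float
    GC2: float
    GC3: float
    GC12: float

    @property
    def defined_flags(self) -> dict[str, bool]:
        return {f.name: not np.isnan(getattr(self, f.name)) for f in fields(self)}

    def as_series(self) -> pd.Series:
        return pd.Series({name: getattr(self, name) for name in INDEX_NAMES})


def _as_array(counts) -> np.ndarray:
    arr = np.asarray(
        counts.reindex(list(CODONS)).fillna(0) if isinstance(counts, pd.Series) else counts,
        dtype=float,
    )
    if arr.shape != (64,):
        raise ValueError("counts must be a 64-vector in standard codon order")
    return arr


def gc_whole(counts, code: GeneticCode = STANDARD_CODE) -> float:
    """G+C fraction over all three positions of counted sense codons.

    Stop codons are excluded; Met and Trp are included (whole-gene
    content, not a synonymous measure). NaN when no sense codons.
    """
    arr = _as_array(counts)
    gc_bases = 0.0
    total = 0.0
    for i, codon in enumerate(CODONS):
        if codon in code.stop_codons or arr[i] == 0:
            continue
        gc_bases += arr[i] * sum(b in "GC" for b in codon)
        total += arr[i]
    if total == 0:
        return float("nan")
    return gc_bases / (3.0 * total)


def positional_gc(counts, code: GeneticCode = STANDARD_CODE) -> tuple[float, float, float]:
    """(GC1, GC2, GC3): fraction of sense codons with G/C at each position."""
    arr = _as_array(counts)
    num = [0.0, 0.0, 0.0]
    total = 0.0
    for i, codon in enumerate(CODONS):
        if codon in code.stop_codons or arr[i] == 0:
            continue
        total += arr[i]
        for k in range(3):
            if codon[k] in "GC":
                num[k] += arr[i]
    if total == 0:
        return (float("nan"),) * 3
    return tuple(n / total for n in num)  # type: ignore[return-value]


def synonymous_third_freqs(
    counts, code: GeneticCode = STANDARD_CODE
) -> tuple[float, float, float, float, float]:
    """(A3s, T3s, G3s, C3s, GC3s) with family-potential denominators.

    For base X: numerator = synonymous codons ending in X; denominator =
    synonymous codons whose amino-acid family contains an X-ending codon.
    GC3s = G/C-ending synonymous codons over all synonymous codons.
    """
    arr = _as_array(counts)
    num = dict.fromkeys("ACGT", 0.0)
    den = dict.fromkeys("ACGT", 0.0)
    syn_total = 0.0
    gc_end = 0.0
    for aa, family in code.families.items():
        if len(family) < 2:
            continue
        fam_counts = {c: arr[CODONS.index(c)] for c in family}
        fam_total = sum(fam_counts.values())
        if fam_total == 0:
            continue
        syn_total += fam_total
        third_bases = {c[2] for c in family}
        for base in "ACGT":
            if base in third_bases:
                den[base] += fam_total
                num[base] += sum(v for c, v in fam_counts.items() if c[2] == base)
        gc_end += sum(v for c, v in fam_counts.items() if c[2] in "GC")
    def frac(n, d):
        return n / d if d > 0 else float("nan")
    return (
        frac(num["A"], den["A"]),
        frac(num["T"], den["T"]),
        frac(num["G"], den["G"]),
        frac(num["C"], den["C"]),
        frac(gc_end, syn_total) if syn_total > 0 else float("nan"),
    )


def composition_profile(counts, code: GeneticCode = STANDARD_CODE) -> CompositionProfile:
    """Full :class:`CompositionProfile` for one 64-vector of counts."""
    a3s, t3s, g3s, c3s, gc3s = synonymous_third_freqs(counts, code)
    gc1, gc2, gc3 = positional_gc(counts, code)
    gc12 = (gc1 + gc2) / 2.0
    return CompositionProfile(
        T3s=t3s, A3s=a3s, G3s=g3s, C3s=c3s, GC3s=gc3s,
        GC=gc_whole(counts, code), GC1=gc1, GC2=gc2, GC3=gc3, GC12=gc12,
    )


def profile_table(table: CodonCountTable, code: GeneticCode = STANDARD_CODE) -> pd.DataFrame:
    """Per-gene composition profiles as a DataFrame (one row per gene)."""
    rows = {gid: composition_profile(row.to_numpy(), code).as_series()
            for gid, row in table.per_gene.iterrows()}
    return pd.DataFrame.from_dict(rows, orient="index").reindex(columns=list(INDEX_NAMES))


def pooled_profile(table: CodonCountTable, code: GeneticCode = STANDARD_CODE) -> CompositionProfile:
    """Profile of the pooled counts (count-weighted; not a mean of genes)."""
    return composition_profile(table.pooled.to_numpy(), code)
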
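"""Codon-usage-bias indices: RSCU, ENC, the expected-ENC curve, PR2 and P2.

RSCU
    Observed codon count divided by the count expected if all synonyms of
    its amino acid were used equally: ``RSCU(c) = n_c * k / n_aa`` for a
    family of ``k`` codons. 1 means unbiased; the values within a used
    family always sum to ``k``.

ENC (effective number of codons, Nc)
    Wright's measure of departure from uniform synonymous usage. Per
    amino-acid family with usage ``n >= 2`` the codon homozygosity is
    ``F = (n * sum(p_i^2) - 1) / (n - 1)``; class means F2..F6 over the
    families of each degeneracy class combine to
    ``ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6``.
    20 = one codon per amino acid, 61 = all synonyms used equally;
    finite-sample values above 61 are capped.

Expected ENC
    The null curve of ENC as a function of GC3s (``s``) when bias comes
    from third-position base composition alone:
    ``ENC_exp(s) = 2 + s + 29 / (s^2 + (1-s)^2)``.

PR2
    Third-position parity coordinates ``(G3s/(G3s+C3s), A3s/(A3s+T3s))``;
    (0.5, 0.5) is the point where A = T and G = C, the expectation under
    strand-symmetric mutation with no selection.

P2
    Frequency of the "correct" pyrimidine at the third position in
    weak/strong first-two-base contexts, computed from RSCU sums:
    ``P2 = (WWC + SSU) / (WWC + WWU + SSC + SSU)`` where W = A/U, S = C/G.
    Values above 0.5 indicate translational selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import CompositionProfile
from .genetic_code import CODON_INDEX, CODONS, GeneticCode, STANDARD_CODE, to_rna
from .seqio import CodonCountTable

ENC_MIN, ENC_MAX = 20.0, 61.0


# ---------------------------------------------------------------------------
# RSCU
# ---------------------------------------------------------------------------

def rscu(counts, code: GeneticCode = STANDARD_CODE) -> pd.Series:
    """RSCU for the 59 synonymous codons as a Series (NaN = family unused).

    Met, Trp and stop codons are excluded by definition. The Series index
    is DNA codons in standard order; use :func:`cubkit.genetic_code.to_rna`
    when printing.
    """
    arr = _counts_array(counts)
    out = {}
    for aa, family in code.families.items():
        k = len(family)
        if k < 2:
            continue
        total = sum(arr[CODON_INDEX[c]] for c in family)
        for c in family:
            out[c] = arr[CODON_INDEX[c]] * k / total if total > 0 else float("nan")
    return pd.Series(out).reindex([c for c in CODONS if c in out])


def rscu_table(table: CodonCountTable, code: GeneticCode = STANDARD_CODE) -> pd.DataFrame:
    """Per-gene RSCU values: one row per gene, one column per synonymous codon."""
    return pd.DataFrame(
        {gid: rscu(row.to_numpy(), code) for gid, row in table.per_gene.iterrows()}
    ).T


def _counts_array(counts) -> np.ndarray:
    if isinstance(counts, pd.Series):
        counts = counts.reindex(list(CODONS)).fillna(0).to_numpy()
    arr = np.asarray(counts, dtype=float)
    if arr.shape != (64,):
        raise ValueError("counts must be a 64-vector in standard codon order")
    return arr


# ---------------------------------------------------------------------------
# ENC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ENCResult:
    """Wright's ENC with its per-class mean homozygosities."""

    enc: float                           # NaN when undefined
    class_homozygosity: dict[int, float]  # degeneracy class -> mean F
    n_missing_families: int              # families with usage < 2
    raw_enc: float                       # before capping at 61
    reason: str | None = None            # why undefined, if so

    @property
    def defined(self) -> bool:
        return not np.isnan(self.enc)


def enc(counts, code: GeneticCode = STANDARD_CODE) -> ENCResult:
    """Effective number of codons from a 64-vector of counts.

    A family with usage below 2 contributes no homozygosity. If the
    three-fold class (Ile) is empty it is imputed as the mean of the
    two-fold and four-fold class means; any other empty class leaves ENC
    undefined.
    """
    arr = _counts_array(counts)
    F_lists: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    n_missing = 0
    for aa, family in code.families.items():
        k = len(family)
        if k < 2:
            continue
        fam = np.array([arr[CODON_INDEX[c]] for c in family], dtype=float)
        n = fam.sum()
        if n < 2:
            n_missing += 1
            continue
        p = fam / n
        F = (n * float(np.sum(p * p)) - 1.0) / (n - 1.0)
        F_lists[k].append(F)
    Fbar = {k: (float(np.mean(v)) if v else float("nan")) for k, v in F_lists.items()}
    class_counts = {2: 9, 3: 1, 4: 5, 6: 3}
    if np.isnan(Fbar[3]) and not np.isnan(Fbar[2]) and not np.isnan(Fbar[4]):
        Fbar[3] = (Fbar[2] + Fbar[4]) / 2.0
    undefined = None
    if any(np.isnan(Fbar[k]) for k in class_counts):
        undefined = "degeneracy class with no usable family"
    elif any(Fbar[k] <= 0 for k in class_counts):
        undefined = "non-positive mean homozygosity in some class"
    if undefined:
        return ENCResult(float("nan"), Fbar, n_missing, float("nan"), undefined)
    raw = 2.0 + sum(class_counts[k] / Fbar[k] for k in class_counts)
    return ENCResult(min(raw, ENC_MAX), Fbar, n_missing, raw)


def enc_table(table: CodonCountTable, code: GeneticCode = STANDARD_CODE) -> pd.Series:
    """Per-gene ENC values (NaN where undefined)."""
    return pd.Series(
        {gid: enc(row.to_numpy(), code).enc for gid, row in table.per_gene.iterrows()},
        name="ENC",
    )


def expected_enc(s):
    """Expected ENC under pure third-position compositional bias.

    Accepts a scalar or array of GC3s values in [0, 1].
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any((s_arr < 0) | (s_arr > 1)):
        raise ValueError("GC3s must lie in [0, 1]")
    val = 2.0 + s_arr + 29.0 / (s_arr**2 + (1.0 - s_arr) ** 2)
    return float(val) if np.isscalar(s) else val


# ---------------------------------------------------------------------------
# PR2
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PR2Point:
    """One gene's parity-rule-2 coordinates (x: G vs C, y: A vs T)."""

    x: float
    y: float


def pr2_point(profile: CompositionProfile) -> PR2Point:
    """PR2 coordinates from a composition profile's X3s values."""
    gs, cs = profile.G3s, profile.C3s
    a, t = profile.A3s, profile.T3s
    x = gs / (gs + cs) if (gs + cs) > 0 else float("nan")
    y = a / (a + t) if (a + t) > 0 else float("nan")
    return PR2Point(x=x, y=y)


# ---------------------------------------------------------------------------
# P2
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class P2Result:
    """The four context RSCU sums and the P2 translational-selection index."""

    WWC: float
    SSU: float
    WWU: float
    SSC: float
    P2: float

    @classmethod
    def from_sums(cls, wwc: float, ssu: float, wwu: float, ssc: float) -> "P2Result":
        den = wwc + wwu + ssc + ssu
        p2 = (wwc + ssu) / den if den > 0 else float("nan")
        return cls(WWC=wwc, SSU=ssu, WWU=wwu, SSC=ssc, P2=p2)


def p2_eligible_pairs(code: GeneticCode = STANDARD_CODE) -> list[tuple[str, str]]:
    """(C-ending, T-ending) codon pairs entering P2.

    A pair qualifies when its first two bases are both weak (A/T) or both
    strong (G/C) and the two pyrimidine-ending codons are synonymous.
    """
    pairs = []
    for c_codon in CODONS:
        if not c_codon.endswith("C"):
            continue
        prefix = c_codon[:2]
        if not (set(prefix) <= set("AT") or set(prefix) <= set("GC")):
            continue
        t_codon = prefix + "T"
        aa_c = code.codon_to_aa.get(c_codon)
        aa_t = code.codon_to_aa.get(t_codon)
        if aa_c == aa_t and aa_c not in (None, "*"):
            pairs.append((c_codon, t_codon))
    return pairs


def p2_index(rscu_values: pd.Series, code: GeneticCode = STANDARD_CODE) -> P2Result:
    """P2 from an RSCU Series (typically pooled over a gene set).

    NaN RSCU entries (absent families) are skipped; the index is undefined
    only if the denominator sum is empty.
    """
    www = {"WWC": 0.0, "WWU": 0.0, "SSC": 0.0, "SSU": 0.0}
    for c_codon, t_codon in p2_eligible_pairs(code):
        weak = set(c_codon[:2]) <= set("AT")
        rc = rscu_values.get(c_codon, float("nan"))
        rt = rscu_values.get(t_codon, float("nan"))
        if not np.isnan(rc):
            www["WWC" if weak else "SSC"] += rc
        if not np.isnan(rt):
            www["WWU" if weak else "SSU"] += rt
    return P2Result.from_sums(www["WWC"], www["SSU"], www["WWU"], www["SSC"])


def per_gene_index_table(
    table: CodonCountTable, code: GeneticCode = STANDARD_CODE
) -> pd.DataFrame:
    """Composition profile + ENC + PR2 coordinates per gene, one wide table."""
    from .composition import composition_profile

    rows = []
    for gid, row in table.per_gene.iterrows():
        arr = row.to_numpy()
        prof = composition_profile(arr, code)
        point = pr2_point(prof)
        rec = prof.as_series().to_dict()
        rec["ENC"] = enc(arr, code).enc
        rec["PR2_x"] = point.x
        rec["PR2_y"] = point.y
        rec["n_codons"] = int(arr.sum())
        rows.append(pd.Series(rec, name=gid))
    return pd.DataFrame(rows)
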
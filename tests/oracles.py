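"""Brute-force reference implementations used only in tests.

Everything here is written from first principles over a hard-coded
standard-code literal and plain Python loops, independent of the package's
GeneticCode machinery, so agreement is a genuine two-route check.
Counts are plain dicts codon -> int.
"""

from __future__ import annotations

import math

STANDARD_CODE = {
    "AAA": "K", "AAC": "N", "AAG": "K", "AAT": "N", "ACA": "T", "ACC": "T", "ACG": "T", "ACT": "T",
    "AGA": "R", "AGC": "S", "AGG": "R", "AGT": "S", "ATA": "I", "ATC": "I", "ATG": "M", "ATT": "I",
    "CAA": "Q", "CAC": "H", "CAG": "Q", "CAT": "H", "CCA": "P", "CCC": "P", "CCG": "P", "CCT": "P",
    "CGA": "R", "CGC": "R", "CGG": "R", "CGT": "R", "CTA": "L", "CTC": "L", "CTG": "L", "CTT": "L",
    "GAA": "E", "GAC": "D", "GAG": "E", "GAT": "D", "GCA": "A", "GCC": "A", "GCG": "A", "GCT": "A",
    "GGA": "G", "GGC": "G", "GGG": "G", "GGT": "G", "GTA": "V", "GTC": "V", "GTG": "V", "GTT": "V",
    "TAA": "*", "TAC": "Y", "TAG": "*", "TAT": "Y", "TCA": "S", "TCC": "S", "TCG": "S", "TCT": "S",
    "TGA": "*", "TGC": "C", "TGG": "W", "TGT": "C", "TTA": "L", "TTC": "F", "TTG": "L", "TTT": "F",
}

FAMILIES: dict[str, list[str]] = {}
for _codon, _aa in sorted(STANDARD_CODE.items()):
    if _aa != "*":
        FAMILIES.setdefault(_aa, []).append(_codon)

MULTI_FAMILIES = {aa: cs for aa, cs in FAMILIES.items() if len(cs) >= 2}


def oracle_rscu(counts: dict[str, float]) -> dict[str, float]:
    out = {}
    for aa, fam in MULTI_FAMILIES.items():
        total = sum(counts.get(c, 0) for c in fam)
        for c in fam:
            out[c] = counts.get(c, 0) * len(fam) / total if total > 0 else math.nan
    return out


def oracle_enc(counts: dict[str, float]) -> float:
    """Wright's ENC recomputed symbol by symbol; NaN if a class is unusable
    (no imputation: oracle-equivalence inputs keep every family populated)."""
    by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, fam in MULTI_FAMILIES.items():
        n = sum(counts.get(c, 0) for c in fam)
        if n < 2:
            continue
        sum_p2 = sum((counts.get(c, 0) / n) ** 2 for c in fam)
        F = (n * sum_p2 - 1.0) / (n - 1.0)
        by_class[len(fam)].append(F)
    enc = 2.0
    for k, weight in ((2, 9), (3, 1), (4, 5), (6, 3)):
        Fs = by_class[k]
        if not Fs:
            return math.nan
        Fbar = sum(Fs) / len(Fs)
        if Fbar <= 0:
            return math.nan
        enc += weight / Fbar
    return min(enc, 61.0)


def oracle_x3s(counts: dict[str, float]) -> dict[str, float]:
    """A3s/T3s/G3s/C3s with family-potential denominators, plus GC3s."""
    num = dict.fromkeys("ACGT", 0.0)
    den = dict.fromkeys("ACGT", 0.0)
    syn = 0.0
    gc_end = 0.0
    for aa, fam in MULTI_FAMILIES.items():
        fam_total = sum(counts.get(c, 0) for c in fam)
        if fam_total == 0:
            continue
        syn += fam_total
        offered = {c[2] for c in fam}
        for base in "ACGT":
            if base in offered:
                den[base] += fam_total
                num[base] += sum(counts.get(c, 0) for c in fam if c[2] == base)
        gc_end += sum(counts.get(c, 0) for c in fam if c[2] in "GC")
    out = {
        f"{b}3s": (num[b] / den[b] if den[b] > 0 else math.nan) for b in "ATGC"
    }
    out["GC3s"] = gc_end / syn if syn > 0 else math.nan
    return out


def oracle_p2(rscu_values: dict[str, float]) -> float:
    """P2 by direct enumeration of qualifying pyrimidine pairs."""
    weak, strong = set("AT"), set("GC")
    wwc = wwu = ssc = ssu = 0.0
    for c_codon, aa in STANDARD_CODE.items():
        if aa == "*" or not c_codon.endswith("C"):
            continue
        prefix = c_codon[:2]
        t_codon = prefix + "T"
        if STANDARD_CODE.get(t_codon) != aa:
            continue
        if set(prefix) <= weak:
            wwc += rscu_values[c_codon]
            wwu += rscu_values[t_codon]
        elif set(prefix) <= strong:
            ssc += rscu_values[c_codon]
            ssu += rscu_values[t_codon]
    return (wwc + ssu) / (wwc + wwu + ssc + ssu)


def oracle_pearson(x, y) -> float:
    """Plain covariance / (sigma_x sigma_y)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / n)
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / n)
    return cov / (sx * sy)
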
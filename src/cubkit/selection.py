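"""Putative optimal-codon determination and RSCU frequency classes.

Genes are ranked by ENC; the lowest 5% (strongest bias, an expression
proxy) form the high-bias dataset and the highest 5% the low-bias
dataset. For each synonymous codon the pooled RSCU of the two datasets is
compared: a codon is called optimal when its usage is significantly
higher in the high-bias set (Welch two-sample t-test on per-gene RSCU,
P < 0.01) and the pooled difference ``dRSCU = RSCU_high - RSCU_low`` is
at least 0.08 (inclusive threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import GeneticCode, STANDARD_CODE, to_rna
from .indices import rscu, rscu_table
from .seqio import CodonCountTable


@dataclass(frozen=True)
class BiasPartition:
    """The ENC-extreme gene datasets used for optimal-codon detection."""

    high_bias_ids: tuple[str, ...]   # lowest-ENC tail (strong bias)
    low_bias_ids: tuple[str, ...]    # highest-ENC tail (weak bias)
    fraction: float

    def __post_init__(self):
        if set(self.high_bias_ids) & set(self.low_bias_ids):
            raise ValueError("high- and low-bias gene sets overlap")


def partition_by_enc(per_gene_enc, fraction: float = 0.05) -> BiasPartition:
    """Split genes into the two ENC-extreme datasets.

    ``per_gene_enc`` maps gene_id -> ENC (NaN entries are dropped). Ties
    at either cut are broken by gene id so the partition is deterministic
    under input reordering. Each tail holds ``floor(fraction * n)`` genes,
    at least 1 when two or more genes are available.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    series = pd.Series(dict(per_gene_enc)).dropna()
    n = len(series)
    if n < 2:
        raise ValueError("need at least 2 genes with defined ENC")
    m = max(1, math.floor(fraction * n))
    ordered = sorted(series.items(), key=lambda kv: (kv[1], kv[0]))
    high = tuple(gid for gid, _ in ordered[:m])
    low = tuple(gid for gid, _ in ordered[n - m:])
    return BiasPartition(high_bias_ids=high, low_bias_ids=low, fraction=fraction)


def optimal_codons(
    counts: CodonCountTable,
    partition: BiasPartition,
    code: GeneticCode = STANDARD_CODE,
    delta_threshold: float = 0.08,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-codon optimal-codon report.

    Columns: ``codon`` (RNA form), ``amino_acid``, ``rscu_high``,
    ``rscu_low`` (pooled within each dataset), ``delta_rscu``, ``p_value``
    (Welch t on per-gene RSCU; genes lacking the family are omitted),
    ``optimal`` and ``testable``. The index is the DNA codon.
    """
    if not partition.high_bias_ids or not partition.low_bias_ids:
        raise ValueError("both partition datasets must be non-empty")
    high = counts.subset(partition.high_bias_ids)
    low = counts.subset(partition.low_bias_ids)
    rscu_high = rscu(high.pooled, code)
    rscu_low = rscu(low.pooled, code)
    per_gene_high = rscu_table(high, code)
    per_gene_low = rscu_table(low, code)

    rows = []
    for codon in rscu_high.index:
        rh, rl = rscu_high[codon], rscu_low[codon]
        xs = per_gene_high[codon].dropna().to_numpy()
        ys = per_gene_low[codon].dropna().to_numpy()
        testable = not (np.isnan(rh) or np.isnan(rl)) and len(xs) >= 2 and len(ys) >= 2
        if testable:
            if np.ptp(xs) == 0 and np.ptp(ys) == 0:
                p = 1.0 if xs[0] == ys[0] else 0.0
            else:
                p = float(stats.ttest_ind(xs, ys, equal_var=False).pvalue)
            delta = rh - rl
            optimal = (delta >= delta_threshold) and (p < alpha) and (rh > rl)
        else:
            p, delta, optimal = float("nan"), rh - rl, False
        rows.append(
            {
                "codon": to_rna(codon),
                "amino_acid": code.codon_to_aa[codon],
                "rscu_high": rh,
                "rscu_low": rl,
                "delta_rscu": delta,
                "p_value": p,
                "optimal": bool(optimal),
                "testable": bool(testable),
            }
        )
    report = pd.DataFrame(rows, index=list(rscu_high.index))
    report.index.name = "codon_dna"
    return report


def frequency_classes(rscu_values: pd.Series, tol: float = 0.0) -> pd.Series:
    """Classify each codon as high (RSCU>1), low (<1), unbiased (=1) or undefined."""
    def classify(v: float) -> str:
        if np.isnan(v):
            return "undefined"
        if v > 1.0 + tol:
            return "high"
        if v < 1.0 - tol:
            return "low"
        return "unbiased"

    return rscu_values.map(classify).rename("frequency_class")
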
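"""Cross-genome statistics: index correlations, ANOVA with Duncan's
multiple range test, and hierarchical clustering of gene sets by RSCU.

Duncan's multiple range test compares group means after a one-way ANOVA
using studentized-range critical values at the protection level
``1 - (1 - alpha)^(p - 1)`` for a range spanning ``p`` ordered means, with
the pooled error mean square and (for unequal group sizes) the harmonic
mean of the sizes. A range contained in a non-significant wider range is
never declared significant. The result is summarised with the usual
letter display: groups sharing a letter do not differ at ``alpha``.
"""

from __future__ import annotations

import io
import itertools
import string
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from skbio import TreeNode

SMALL_SAMPLE_N = 10


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise correlations among CUB indices.

    ``table`` is long-form with columns index_a, index_b, r, p_value, n;
    it contains each unordered pair once plus the unit diagonal.
    """

    table: pd.DataFrame

    def matrix(self, field: str = "r") -> pd.DataFrame:
        """Square symmetric matrix of ``field`` (r, p_value or n)."""
        names = pd.unique(self.table[["index_a", "index_b"]].to_numpy().ravel())
        mat = pd.DataFrame(np.nan, index=names, columns=names)
        for _, row in self.table.iterrows():
            mat.loc[row.index_a, row.index_b] = row[field]
            mat.loc[row.index_b, row.index_a] = row[field]
        return mat


def correlate_indices(
    per_gene: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] | None = None,
    method: str = "pearson",
) -> CorrelationMatrix:
    """Product-moment correlations with two-tailed p-values.

    Undefined entries are handled pairwise-complete. Pairs with fewer
    than 3 complete observations, or with a constant column, yield NaN.
    A small-sample warning is emitted below 10 observations (whole-genome
    correlations across a handful of gene sets are supported but weak).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    cols = list(per_gene.columns)
    if pairs is None:
        pairs = list(itertools.combinations(cols, 2))
    rows = []
    for a in cols:
        rows.append({"index_a": a, "index_b": a, "r": 1.0, "p_value": 0.0,
                     "n": int(per_gene[a].notna().sum())})
    for a, b in pairs:
        sub = per_gene[[a, b]].dropna()
        n = len(sub)
        r = p = float("nan")
        if n < 3:
            warnings.warn(f"{a}~{b}: only {n} complete observations", stacklevel=2)
        elif sub[a].nunique() < 2 or sub[b].nunique() < 2:
            pass  # constant column: undefined
        else:
            if n < SMALL_SAMPLE_N:
                warnings.warn(
                    f"{a}~{b}: correlation on only {n} observations", stacklevel=2
                )
            fn = stats.pearsonr if method == "pearson" else stats.spearmanr
            res = fn(sub[a], sub[b])
            r, p = float(res.statistic), float(res.pvalue)
        rows.append({"index_a": a, "index_b": b, "r": r, "p_value": p, "n": n})
    return CorrelationMatrix(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# ANOVA + Duncan's multiple range test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MultipleComparisonResult:
    """One-way ANOVA plus Duncan letter display.

    ``summary`` has one row per group, ordered by descending mean, with
    columns group, n, mean, sd, letters. Groups sharing any letter are not
    significantly different at ``alpha``.
    """

    summary: pd.DataFrame
    f_statistic: float
    p_value: float
    alpha: float
    ms_error: float
    df_error: int
    critical_ranges: dict[int, float]

    def letters(self) -> dict[str, str]:
        return dict(zip(self.summary["group"], self.summary["letters"]))


def _duncan_nonsig_intervals(
    means: np.ndarray, ranges: dict[int, float]
) -> list[tuple[int, int]]:
    """Maximal non-significant index intervals over descending means."""
    k = len(means)
    nonsig: list[tuple[int, int]] = []

    def covered(i, j):
        return any(a <= i and j <= b for a, b in nonsig)

    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if covered(i, j):
                continue
            if not (means[i] - means[j] > ranges[span]):
                nonsig.append((i, j))
    # singletons for groups in no interval
    for i in range(k):
        if not covered(i, i):
            nonsig.append((i, i))
    nonsig.sort()
    return nonsig


def anova_duncan(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> MultipleComparisonResult:
    """One-way ANOVA followed by Duncan's multiple range test.

    ``groups`` maps label -> per-gene values (NaN dropped). Requires at
    least two groups with at least two values each.
    """
    data = {lab: np.asarray(pd.Series(v).dropna(), dtype=float) for lab, v in groups.items()}
    if len(data) < 2:
        raise ValueError("need at least 2 groups")
    for lab, v in data.items():
        if len(v) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 values")
    labels = list(data)
    ns = np.array([len(data[g]) for g in labels])
    means = np.array([data[g].mean() for g in labels])
    sds = np.array([data[g].std(ddof=1) for g in labels])
    N, k = int(ns.sum()), len(labels)
    grand = np.concatenate([data[g] for g in labels]).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((data[g] - data[g].mean()) ** 2) for g in labels))
    df_b, df_e = k - 1, N - k
    ms_between = ss_between / df_b
    ms_error = ss_within / df_e
    if ms_error == 0.0:
        f_stat = float("inf") if ms_between > 0 else float("nan")
        p_value = 0.0 if ms_between > 0 else 1.0
    else:
        f_stat = ms_between / ms_error
        p_value = float(stats.f.sf(f_stat, df_b, df_e))

    # Duncan critical ranges; harmonic mean of sizes for unequal n
    n_h = k / np.sum(1.0 / ns)
    se = np.sqrt(ms_error / n_h)
    ranges = {}
    for span in range(2, k + 1):
        protection = 1.0 - (1.0 - alpha) ** (span - 1)
        q = stats.studentized_range.ppf(1.0 - protection, span, df_e)
        ranges[span] = float(q * se)

    order = np.lexsort((labels, -means))  # descending mean, label tie-break
    ordered_labels = [labels[i] for i in order]
    ordered_means = means[order]
    intervals = _duncan_nonsig_intervals(ordered_means, ranges)
    letter_of_interval = {}
    alphabet = itertools.chain(
        string.ascii_lowercase,
        ("".join(p) for p in itertools.product(string.ascii_lowercase, repeat=2)),
    )
    for iv in intervals:
        letter_of_interval[iv] = next(alphabet)
    letter_strings = []
    for pos in range(k):
        letters = "".join(
            letter_of_interval[iv] for iv in intervals if iv[0] <= pos <= iv[1]
        )
        letter_strings.append(letters)
    summary = pd.DataFrame(
        {
            "group": ordered_labels,
            "n": ns[order],
            "mean": ordered_means,
            "sd": sds[order],
            "letters": letter_strings,
        }
    )
    return MultipleComparisonResult(
        summary=summary,
        f_statistic=f_stat,
        p_value=p_value,
        alpha=alpha,
        ms_error=ms_error,
        df_error=df_e,
        critical_ranges=ranges,
    )


# ---------------------------------------------------------------------------
# RSCU clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterTree:
    """Agglomerative tree over labelled RSCU vectors."""

    labels: tuple[str, ...]
    linkage: np.ndarray            # scipy linkage matrix
    data: pd.DataFrame             # imputed vectors actually clustered

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage, list(self.labels))
        buf = io.StringIO()
        tree.write(buf, format="newick")
        return buf.getvalue().strip()

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def rscu_cluster(
    rscu_by_set: Mapping[str, pd.Series],
    metric: str = "euclidean",
    method: str = "average",
) -> ClusterTree:
    """Hierarchical clustering of gene sets by their pooled RSCU vectors.

    Vectors are aligned on their shared codon index. Entries undefined in
    some sets are imputed with the across-set mean for that codon; codons
    undefined everywhere are dropped. Labels are processed in sorted order
    so the tree is deterministic under input reordering.
    """
    if len(rscu_by_set) < 2:
        raise ValueError("need at least 2 labelled RSCU vectors")
    labels = tuple(sorted(rscu_by_set))
    mat = pd.DataFrame({lab: pd.Series(rscu_by_set[lab]) for lab in labels}).T
    mat = mat.dropna(axis=1, how="all")
    mat = mat.fillna(mat.mean(axis=0))
    Z = _scipy_linkage(mat.to_numpy(), method=method, metric=metric)
    return ClusterTree(labels=labels, linkage=Z, data=mat)
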
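"""Synthetic CDS sets with known codon-usage ground truth.

The generator emulates the two forces the downstream indices are designed
to separate:

* **Mutation pressure** — a third-position base-composition bias. For an
  unselected codon the amino acid is drawn from ``aa_frequencies`` and a
  family codon is drawn with probability proportional to the mutational
  probability of its third base (``mutation_third_base_probs`` restricted
  and renormalized to the third bases the family offers). Under uniform
  base probabilities every family — including the six-fold ones — is
  therefore used uniformly, the RSCU = 1 neutral limit.
* **Translational selection** — with per-gene probability ``s_g`` the
  designated preferred codon of the drawn amino acid is emitted instead.

Each gene is ``ATG`` + L sense codons + one stop. ``s_g = 0`` genes sit on
the expected-ENC curve (up to sampling noise); ``s_g = 1`` genes collapse
every family to its preferred codon, the ENC = 20 limit. The
:class:`TruthTable` records per-gene ``s_g`` so recovery of the preferred
set by the optimal-codon procedure can be scored exactly.

The generator produces equilibrium snapshots only; it does not simulate
mutation-selection-drift dynamics over generations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .genetic_code import GeneticCode, STANDARD_CODE
from .indices import enc_table, expected_enc
from .seqio import CodonCountTable, GeneRecord


def default_preferred_codons(code: GeneticCode = STANDARD_CODE) -> dict[str, str]:
    """One designated preferred codon per multi-codon amino acid.

    Deterministic default: the alphabetically first codon of each family.
    """
    return {
        aa: fam[0] for aa, fam in code.families.items() if len(fam) >= 2
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the mutation-selection CDS generator.

    Defaults describe the standard study condition used throughout the
    test-bed: 400 genes of ~400 codons, uniform amino-acid usage over the
    18 multi-codon amino acids, no third-base mutational skew, and a
    two-point selection mixture in which 12.5% of genes are strongly
    selected (s_g = 0.8) toward the preferred-codon set and the rest are
    neutral.
    """

    n_genes: int = 400
    length_mean: float = 400.0       # codons, excluding start/stop
    length_sd: float = 100.0
    length_min: int = 30
    aa_frequencies: Mapping[str, float] | None = None   # None = uniform multi-codon aas
    mutation_third_base_probs: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    )
    preferred_codons: Mapping[str, str] | None = None   # None = alphabetic default
    selection_values: tuple[float, ...] = (0.0, 0.8)    # two-point mixture of s_g
    selection_weights: tuple[float, ...] = (0.875, 0.125)
    stratify_selection: bool = True   # exact stratum sizes (largest remainder), rng-permuted
    seed: int = 0

    def validate(self, code: GeneticCode = STANDARD_CODE) -> None:
        problems = []
        if self.n_genes < 1:
            problems.append("n_genes must be >= 1")
        if self.length_min < 1 or self.length_mean <= 0:
            problems.append("gene length rule must be positive")
        probs = self.mutation_third_base_probs
        if set(probs) != set("ACGT") or abs(sum(probs.values()) - 1.0) > 1e-9:
            problems.append("mutation_third_base_probs must cover ACGT and sum to 1")
        if any(p < 0 for p in probs.values()):
            problems.append("mutation_third_base_probs must be non-negative")
        if len(self.selection_values) != len(self.selection_weights):
            problems.append("selection_values and selection_weights differ in length")
        if any(not 0 <= s <= 1 for s in self.selection_values):
            problems.append("selection values must lie in [0, 1]")
        if abs(sum(self.selection_weights) - 1.0) > 1e-9:
            problems.append("selection_weights must sum to 1")
        pref = self.preferred_codons or default_preferred_codons(code)
        for aa, fam in code.families.items():
            if len(fam) >= 2 and pref.get(aa) not in fam:
                problems.append(f"no valid preferred codon for amino acid {aa}")
        if self.aa_frequencies is not None:
            if abs(sum(self.aa_frequencies.values()) - 1.0) > 1e-9:
                problems.append("aa_frequencies must sum to 1")
            unknown = set(self.aa_frequencies) - set(code.families)
            if unknown:
                problems.append(f"unknown amino acids in aa_frequencies: {sorted(unknown)}")
        if problems:
            raise ValueError("invalid SimulationConfig: " + "; ".join(problems))

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["aa_frequencies"] = dict(self.aa_frequencies) if self.aa_frequencies else None
        d["mutation_third_base_probs"] = dict(self.mutation_third_base_probs)
        d["preferred_codons"] = dict(self.preferred_codons) if self.preferred_codons else None
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        for key in ("selection_values", "selection_weights"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class TruthTable:
    """Ground truth for a generated CDS set."""

    per_gene: pd.DataFrame          # gene_id index; columns length_codons, s_g
    preferred_codons: Mapping[str, str]
    config: SimulationConfig

    def to_frame(self) -> pd.DataFrame:
        out = self.per_gene.copy()
        out.insert(0, "gene_id", out.index)
        return out.reset_index(drop=True)


def generate_cds_set(
    config: SimulationConfig, code: GeneticCode = STANDARD_CODE
) -> tuple[list[GeneRecord], TruthTable]:
    """Draw a CDS set under the mutation-selection model.

    Identical config (including seed) yields byte-identical sequences.
    """
    config.validate(code)
    rng = np.random.default_rng(config.seed)
    pref = dict(config.preferred_codons or default_preferred_codons(code))

    if config.aa_frequencies is None:
        aas = [aa for aa, fam in sorted(code.families.items()) if len(fam) >= 2]
        aa_probs = np.full(len(aas), 1.0 / len(aas))
    else:
        aas = sorted(config.aa_frequencies)
        aa_probs = np.array([config.aa_frequencies[aa] for aa in aas], dtype=float)
        aa_probs = aa_probs / aa_probs.sum()

    # Per amino acid: the codon-emission distribution under pure mutation.
    mut_probs = config.mutation_third_base_probs
    mutation_dist: dict[str, tuple[list[str], np.ndarray]] = {}
    for aa in aas:
        fam = code.families[aa]
        # equilibrium under third-position mutation pressure alone: each
        # codon's weight is the mutational probability of its third base
        # (codons sharing a third base, as in six-fold families, each carry
        # the full base weight), renormalized over the family
        w = np.array([mut_probs[codon[2]] for codon in fam], dtype=float)
        total = w.sum()
        if total == 0:  # mutation bias excludes every base this family offers
            w = np.full(len(fam), 1.0 / len(fam))
        else:
            w = w / total
        mutation_dist[aa] = (list(fam), w)

    stops = sorted(code.stop_codons)
    lengths = np.maximum(
        config.length_min,
        np.rint(rng.normal(config.length_mean, config.length_sd, config.n_genes)).astype(int),
    )
    values = np.array(config.selection_values, dtype=float)
    weights = np.array(config.selection_weights, dtype=float)
    if config.stratify_selection:
        # exact stratum sizes via largest-remainder rounding, then permute
        exact = weights * config.n_genes
        sizes = np.floor(exact).astype(int)
        for i in np.argsort(-(exact - sizes))[: config.n_genes - sizes.sum()]:
            sizes[i] += 1
        s_values = np.repeat(values, sizes)
        rng.shuffle(s_values)
    else:
        s_values = rng.choice(values, size=config.n_genes, p=weights)

    records: list[GeneRecord] = []
    width = len(str(config.n_genes))
    for g in range(config.n_genes):
        L = int(lengths[g])
        s_g = float(s_values[g])
        aa_draw = rng.choice(len(aas), size=L, p=aa_probs)
        selected = rng.random(L) < s_g
        codon_arr = np.empty(L, dtype=object)
        for ai, aa in enumerate(aas):
            pos = np.flatnonzero(aa_draw == ai)
            if pos.size == 0:
                continue
            sel_pos = pos[selected[pos]]
            codon_arr[sel_pos] = pref[aa]
            mut_pos = pos[~selected[pos]]
            if mut_pos.size:
                fam, w = mutation_dist[aa]
                draws = rng.choice(len(fam), size=mut_pos.size, p=w)
                codon_arr[mut_pos] = np.array(fam, dtype=object)[draws]
        stop = stops[rng.integers(0, len(stops))]
        seq = "ATG" + "".join(codon_arr.tolist()) + stop
        gid = f"sim{g:0{width}d}"
        records.append(GeneRecord(gid, f"{gid} s={s_g:g}", seq))

    truth = TruthTable(
        per_gene=pd.DataFrame(
            {"length_codons": lengths, "s_g": s_values},
            index=[r.gene_id for r in records],
        ),
        preferred_codons=pref,
        config=config,
    )
    return records, truth


def recovery_report(
    truth: TruthTable,
    per_gene_enc: pd.Series,
    per_gene_gc3s: pd.Series,
    optimal_report: pd.DataFrame,
    code: GeneticCode = STANDARD_CODE,
) -> pd.Series:
    """Score the analysis pipeline against generator ground truth.

    Reports the rank correlation between per-gene selection strength and
    ENC (expected negative), the fraction of designated preferred codons
    recovered as optimal, the count of family-level false positives
    (optimal codons that are not their family's designated codon), and the
    mean |ENC - ENC_exp(GC3s)| over the neutral (s_g = 0) stratum.
    """
    ids = list(truth.per_gene.index)
    if set(ids) - set(per_gene_enc.index):
        raise ValueError("gene ids in truth table missing from ENC table")
    s_g = truth.per_gene["s_g"]
    enc_vals = per_gene_enc.loc[ids]
    ok = enc_vals.notna() & s_g.notna()
    if s_g[ok].nunique() > 1 and enc_vals[ok].nunique() > 1:
        rho = float(_stats.spearmanr(s_g[ok], enc_vals[ok]).statistic)
    else:
        rho = float("nan")
    preferred = set(truth.preferred_codons.values())
    called = set(optimal_report.index[optimal_report["optimal"]])
    recovered = len(called & preferred) / len(preferred)
    false_family = sum(
        1 for c in called if truth.preferred_codons.get(code.codon_to_aa[c]) != c
    )
    neutral = truth.per_gene.index[s_g == 0.0]
    neutral = [g for g in neutral if not np.isnan(per_gene_enc.get(g, np.nan))]
    if neutral:
        dev = (
            per_gene_enc.loc[neutral]
            - expected_enc(per_gene_gc3s.loc[neutral].to_numpy())
        ).abs()
        mean_dev = float(dev.mean())
    else:
        mean_dev = float("nan")
    return pd.Series(
        {
            "spearman_s_vs_enc": rho,
            "preferred_recovered_fraction": recovered,
            "family_false_positives": float(false_family),
            "neutral_mean_abs_enc_deviation": mean_dev,
            "n_genes": float(len(ids)),
            "n_preferred": float(len(preferred)),
        }
    )
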
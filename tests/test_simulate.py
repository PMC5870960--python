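import numpy as np
import pandas as pd
import pytest

from cubkit import (
    SimulationConfig,
    count_codons,
    default_preferred_codons,
    enc_table,
    generate_cds_set,
    optimal_codons,
    partition_by_enc,
    per_gene_index_table,
    recovery_report,
    rscu,
    validate_and_filter,
)


def _neutral(n_genes, length, seed, probs=None):
    return SimulationConfig(
        n_genes=n_genes,
        length_mean=length,
        length_sd=0.0,
        mutation_third_base_probs=probs or {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25},
        selection_values=(0.0,),
        selection_weights=(1.0,),
        seed=seed,
    )


class TestGenerator:
    def test_same_seed_is_byte_identical(self):
        cfg = SimulationConfig(n_genes=20, length_mean=100, seed=9)
        r1, t1 = generate_cds_set(cfg)
        r2, t2 = generate_cds_set(cfg)
        assert [r.sequence for r in r1] == [r.sequence for r in r2]
        pd.testing.assert_frame_equal(t1.per_gene, t2.per_gene)

    def test_different_seeds_differ(self):
        r1, _ = generate_cds_set(SimulationConfig(n_genes=5, length_mean=50, seed=1))
        r2, _ = generate_cds_set(SimulationConfig(n_genes=5, length_mean=50, seed=2))
        assert [r.sequence for r in r1] != [r.sequence for r in r2]

    def test_sequences_pass_default_filters(self):
        recs, _ = generate_cds_set(SimulationConfig(n_genes=30, length_mean=80, seed=4))
        kept, log = validate_and_filter(recs)
        assert log.n_retained == 30
        assert all(r.sequence.startswith("ATG") for r in recs)

    def test_full_selection_collapses_to_preferred_codons(self):
        cfg = SimulationConfig(
            n_genes=10, length_mean=300, length_sd=0.0,
            selection_values=(1.0,), selection_weights=(1.0,), seed=6,
        )
        recs, truth = generate_cds_set(cfg)
        counts = count_codons(recs)
        encs = enc_table(counts)
        assert np.allclose(encs.to_numpy(), 20.0)
        used = set(counts.pooled[counts.pooled > 0].index) - {"ATG"}
        assert used == set(truth.preferred_codons.values())

    def test_neutral_limit_unbiased(self):
        recs, _ = generate_cds_set(_neutral(50, 800, seed=12))
        counts = count_codons(recs)
        vals = rscu(counts.pooled).dropna()
        # ~2200 codons/family: binomial sd of a six-fold RSCU is ~0.05
        dev = np.abs(vals.to_numpy() - 1.0)
        assert dev.mean() < 0.05
        assert dev.max() < 0.2
        encs = enc_table(counts)
        assert encs.mean() > 57.0

    def test_gc3s_tracks_mutation_bias(self):
        probs = {"A": 0.1, "T": 0.1, "G": 0.4, "C": 0.4}
        recs, _ = generate_cds_set(_neutral(60, 500, seed=13, probs=probs))
        pg = per_gene_index_table(count_codons(recs))
        # family third-base availability distorts the raw 0.8 slightly
        assert abs(pg["GC3s"].mean() - 0.8) < 0.08

    def test_mean_enc_decreases_across_selection_strata(self):
        encs_by_s = {}
        for s in (0.0, 0.4, 0.8):
            cfg = SimulationConfig(
                n_genes=60, length_mean=300, length_sd=0.0,
                selection_values=(s,), selection_weights=(1.0,), seed=14,
            )
            recs, _ = generate_cds_set(cfg)
            encs_by_s[s] = enc_table(count_codons(recs)).mean()
        assert encs_by_s[0.0] > encs_by_s[0.4] > encs_by_s[0.8]

    def test_stratified_selection_gives_exact_counts(self):
        truth = generate_cds_set(SimulationConfig(seed=1))[1]
        assert (truth.per_gene["s_g"] == 0.8).sum() == 50
        assert (truth.per_gene["s_g"] == 0.0).sum() == 350

    def test_invalid_configs_listed(self):
        bad = SimulationConfig(
            n_genes=0,
            mutation_third_base_probs={"A": 0.5, "C": 0.5, "G": 0.2, "T": 0.2},
        )
        with pytest.raises(ValueError, match="n_genes.*sum to 1"):
            bad.validate()

    def test_config_json_round_trip(self):
        cfg = SimulationConfig(n_genes=7, seed=33, selection_values=(0.0, 0.5))
        again = SimulationConfig.from_json(cfg.to_json())
        assert again == cfg

    def test_preferred_codons_default_covers_18_families(self, code):
        pref = default_preferred_codons(code)
        assert len(pref) == 18
        assert all(c in code.families[aa] for aa, c in pref.items())


@pytest.fixture(scope="module")
def pipeline():
    cfg = SimulationConfig(n_genes=200, length_mean=300, length_sd=50, seed=17)
    recs, truth = generate_cds_set(cfg)
    counts = count_codons(recs)
    pg = per_gene_index_table(counts)
    part = partition_by_enc(pg["ENC"])
    report = optimal_codons(counts, part)
    return truth, pg, report


class TestRecoveryReport:
    def test_selection_depresses_enc_rank(self, pipeline):
        truth, pg, report = pipeline
        summary = recovery_report(truth, pg["ENC"], pg["GC3s"], report)
        assert summary["spearman_s_vs_enc"] < -0.3
        assert summary["preferred_recovered_fraction"] >= 0.9
        assert summary["family_false_positives"] == 0

    def test_neutral_stratum_sits_near_expected_curve(self, pipeline):
        truth, pg, report = pipeline
        summary = recovery_report(truth, pg["ENC"], pg["GC3s"], report)
        assert summary["neutral_mean_abs_enc_deviation"] < 4.0  # short genes: loose band

    def test_mismatched_ids_rejected(self, pipeline):
        truth, pg, report = pipeline
        with pytest.raises(ValueError, match="missing"):
            recovery_report(truth, pg["ENC"].iloc[:10], pg["GC3s"], report)

    def test_all_neutral_rank_correlation_undefined_or_tiny(self):
        cfg = _neutral(80, 300, seed=19)
        recs, truth = generate_cds_set(cfg)
        counts = count_codons(recs)
        pg = per_gene_index_table(counts)
        part = partition_by_enc(pg["ENC"])
        report = optimal_codons(counts, part)
        summary = recovery_report(truth, pg["ENC"], pg["GC3s"], report)
        assert np.isnan(summary["spearman_s_vs_enc"])  # s_g constant: no signal
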
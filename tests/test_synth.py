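import math

import numpy as np
import pandas as pd
import pytest

from pseudoclock import rates
from pseudoclock.genotyping import call_genotype
from pseudoclock.screen import detect_lof
from pseudoclock.synth import (
    STOPS,
    EvolvedGene,
    SimConfig,
    evolve_neutral,
    make_gene_set,
    make_read_support,
    simulate_dataset,
    write_fixture,
)


def expected_lof_rate_per_gene(model, reference, config):
    """Analytic per-generation LoF event rate for one gene.

    Derived from first principles independently of the rate module's
    aggregate formulas: stop-gain over interior codons, frameshifting
    indels, splice-dinucleotide hits, start-codon hits, and kappa-weighted
    stop-codon losses.
    """
    kappa = config.kappa
    interior = [
        reference[i : i + 3] for i in range(3, len(reference) - 3, 3)
    ]
    usage = rates.CodonUsage(
        {c: interior.count(c) for c in set(interior)}
    )
    lam_psc = config.mu * (len(reference) - 6) * rates.p_stop(usage, kappa)
    # geometric(0.5) truncated at 10: mass on lengths not divisible by 3
    mass = {k: 0.5**k for k in range(1, 10)}
    mass[10] = 0.5**9
    fs_frac = sum(v for k, v in mass.items() if k % 3 != 0) / sum(mass.values())
    lam_fs = config.indel_rate * len(reference) * fs_frac
    lam_ss = config.mu * 4 * model.intron_count
    lam_ml = config.mu * 3
    stop = reference[-3:]
    n_stop_neighbours = {"TAA": 2 * kappa, "TAG": kappa, "TGA": kappa}[stop]
    lam_sl = config.mu * 3 * (1 - n_stop_neighbours / (3 * (kappa + 2)))
    return lam_psc + lam_fs + lam_ss + lam_ml + lam_sl


class TestMakeGeneSet:
    def test_totals(self):
        gs, seqs = make_gene_set(SimConfig(n_genes=88, gene_length=999, seed=0))
        assert gs.n_genes == 88
        assert gs.total_cds_length == 87_912
        assert gs.total_introns == 88 * 5

    def test_reference_sequences_are_clean_orfs(self):
        gs, seqs = make_gene_set(SimConfig(n_genes=20, gene_length=300, seed=1))
        for gid, seq in seqs.items():
            assert seq.startswith("ATG")
            assert seq[-3:] in STOPS
            internal = [seq[i : i + 3] for i in range(0, len(seq) - 3, 3)]
            assert not any(c in STOPS for c in internal)

    def test_fixture_deterministic_and_byte_identical(self, tmp_path):
        cfg = SimConfig(n_genes=5, gene_length=300, seed=7, g_true=2e5)
        for d in ("a", "b"):
            write_fixture(simulate_dataset(cfg), tmp_path / d)
        for name in (
            "gene_models.tsv",
            "reference.fasta",
            "observed.fasta",
            "truth_lof.tsv",
            "read_support.tsv",
        ):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_zero_introns(self):
        gs, _ = make_gene_set(SimConfig(n_genes=4, n_introns=0, seed=0))
        assert gs.total_introns == 0

    def test_impossible_length_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(gene_length=100)
        with pytest.raises(ValueError):
            SimConfig(gene_length=3)


class TestEvolveNeutral:
    def test_zero_generations_identity(self):
        cfg = SimConfig(n_genes=10, gene_length=300, g_true=0.0, seed=3)
        gs, refs = make_gene_set(cfg)
        evolved, truth = evolve_neutral(gs, refs, cfg)
        assert truth.empty
        for gid, ev in evolved.items():
            assert ev.observed_aln == refs[gid]
            assert ev.observed_introns == [("GT", "AG")] * 5

    def test_pseudogenized_fraction_matches_analytic_expectation(self):
        cfg = SimConfig(n_genes=88, gene_length=999, g_true=2.5e5, seed=0)
        gs, refs = make_gene_set(cfg)
        p_expected = np.mean(
            [
                -math.expm1(
                    -expected_lof_rate_per_gene(m, refs[m.gene_id], cfg)
                    * cfg.g_true
                )
                for m in gs
            ]
        )
        reps = 60
        rng = np.random.default_rng(123)
        fractions = []
        for _ in range(reps):
            _, truth = evolve_neutral(gs, refs, cfg, rng)
            fractions.append(truth["gene_id"].nunique() / cfg.n_genes)
        se = math.sqrt(p_expected * (1 - p_expected) / (reps * cfg.n_genes))
        assert np.mean(fractions) == pytest.approx(p_expected, abs=3 * se)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_screen_recovers_all_truth_events(self, seed):
        cfg = SimConfig(n_genes=40, gene_length=600, g_true=5e5, seed=seed)
        ds = simulate_dataset(cfg)
        detected = {}
        for model in ds["gene_set"]:
            ev = ds["evolved"][model.gene_id]
            muts = detect_lof(
                model, ev.observed_aln, ev.reference_aln, ev.observed_introns
            )
            detected[model.gene_id] = {(m.kind, m.position) for m in muts}
        for row in ds["truth"].itertuples():
            assert (row.kind, row.position) in detected[row.gene_id], (
                row.gene_id,
                row.kind,
                row.position,
                row.detail,
            )

    def test_purity_same_seed_same_truth(self):
        cfg = SimConfig(n_genes=15, gene_length=600, g_true=4e5, seed=21)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        pd.testing.assert_frame_equal(a["truth"], b["truth"])
        assert a["read_support"] == b["read_support"]


class TestMakeReadSupport:
    def test_het_supporting_fraction_near_half(self):
        cfg = SimConfig(seed=5, coverage_mean=1000)
        truth = pd.DataFrame(
            [{"gene_id": "g1", "position": 10, "genotype": "het"}]
        )
        (rec,) = make_read_support(truth, cfg)
        frac = rec.reads_supporting_lof / rec.total_reads
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_hom_truth_zero_error_no_minor_reads(self):
        cfg = SimConfig(seed=6, coverage_mean=30, base_error_rate=0.0)
        truth = pd.DataFrame(
            [
                {"gene_id": "g1", "position": 1, "genotype": "hom_lof"},
                {"gene_id": "g1", "position": 2, "genotype": "hom_ref"},
            ]
        )
        lof_rec, ref_rec = make_read_support(truth, cfg)
        assert lof_rec.reads_opposing_lof == 0
        assert ref_rec.reads_supporting_lof == 0

    def test_genotyper_recovers_truth_at_high_depth(self):
        cfg = SimConfig(seed=8, coverage_mean=200, base_error_rate=0.001)
        truth = pd.DataFrame(
            [
                {"gene_id": "g1", "position": i, "genotype": g}
                for i, g in enumerate(
                    ["hom_lof"] * 20 + ["hom_ref"] * 20 + ["het"] * 20
                )
            ]
        )
        records = make_read_support(truth, cfg)
        correct = 0
        for rec, expected in zip(records, truth["genotype"]):
            call = call_genotype(rec.reads_supporting_lof, rec.reads_opposing_lof)
            correct += call.genotype == expected
        assert correct >= 58  # > 96% concordance at depth 200
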
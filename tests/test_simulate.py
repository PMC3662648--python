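"""Synthetic-data generator: determinism, conservation, sampling laws."""

import numpy as np
import pandas as pd
import pytest

from pikapool.reads import encode_seq
from pikapool.simulate import (
    POOLS,
    PopulationModel,
    RegimeMix,
    SequencingModel,
    generate_reference,
    parse_read_origin,
    simulate_genotype_panel,
    simulate_pool_genotypes,
    simulate_pooled_reads,
)


class TestGenerateReference:
    def test_deterministic_under_fixed_seed(self):
        a = generate_reference(20, 500.0, 80.0, seed=7)
        b = generate_reference(20, 500.0, 80.0, seed=7)
        assert a == b

    def test_seed_changes_output(self):
        a = generate_reference(20, 500.0, 80.0, seed=7)
        b = generate_reference(20, 500.0, 80.0, seed=8)
        assert a != b

    def test_mean_length_tracks_model(self):
        ref = generate_reference(200, 1000.0, 100.0, seed=3)
        lengths = np.array([len(s) for s in ref.values()])
        assert len(ref) == 200
        assert abs(lengths.mean() - 1000.0) / 1000.0 < 0.05

    def test_degenerate_length_model(self):
        ref = generate_reference(10, 300.0, 0.0, seed=5)
        assert all(len(s) == 300 for s in ref.values())

    def test_alphabet(self):
        ref = generate_reference(3, 200.0, seed=1)
        assert all(set(s) <= set("ACGT") for s in ref.values())

    def test_rejects_bad_counts(self):
        with pytest.raises(ValueError):
            generate_reference(0, 100.0)
        with pytest.raises(ValueError):
            generate_reference(5, 0.0)


class TestPopulationModel:
    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError):
            PopulationModel(variable_site_density=0.0)

    def test_regime_weights_validated(self):
        with pytest.raises(ValueError):
            RegimeMix(0.9, 0.9, 0.9)

    def test_json_round_trip(self):
        model = PopulationModel(variable_site_density=0.01, seed=3)
        again = PopulationModel.from_json(model.to_json())
        assert again.variable_site_density == model.variable_site_density
        assert again.seed == model.seed


class TestSimulatePoolGenotypes:
    def _truth(self, spec, seed=0, density=0.01):
        ref = generate_reference(4, 800.0, 0.0, seed=2)
        model = PopulationModel(
            variable_site_density=density, allele_freq_spec=spec, seed=seed
        )
        return simulate_pool_genotypes(model, ref)

    def test_zero_frequency_pool_is_all_reference(self):
        truth = self._truth(lambda rng: (0.0, 0.5))
        gt_cols = [f"gt_high_{i}" for i in range(3)]
        assert (truth.sites[gt_cols].to_numpy() == 0).all()
        assert (truth.sites["alt_count_high"] == 0).all()

    def test_fixed_different_regime_realizes_extreme_frequencies(self):
        truth = self._truth(lambda rng: (1.0, 0.0))
        assert (truth.sites["alt_count_high"] == 6).all()
        assert (truth.sites["alt_count_low"] == 0).all()

    def test_counts_consistent_with_genotypes(self):
        truth = self._truth(RegimeMix(), seed=9)
        for pool in POOLS:
            gt = truth.sites[[f"gt_{pool}_{i}" for i in range(3)]].to_numpy()
            assert (gt.sum(axis=1) == truth.sites[f"alt_count_{pool}"]).all()

    def test_binomial_sampling_mean(self):
        # many replicate sites at f = 0.3: realized mean within 3 SE
        ref = {"tx1": "ACGT" * 5000}
        model = PopulationModel(
            variable_site_density=0.5, allele_freq_spec=lambda rng: (0.3, 0.3), seed=4
        )
        truth = simulate_pool_genotypes(model, ref)
        n_sites = len(truth.sites)
        assert n_sites > 5000
        freqs = truth.sites["alt_count_high"] / 6
        se = np.sqrt(0.3 * 0.7 / 6 / n_sites)
        assert abs(freqs.mean() - 0.3) < 3 * se

    def test_haplotypes_consistent_with_counts(self):
        truth = self._truth(RegimeMix(), seed=5)
        site = truth.sites.iloc[0]
        contig, pos = site["contig"], site["position"]
        alt_idx = "ACGT".index(site["alt_allele"])
        for pool in POOLS:
            n_alt = sum(
                truth.haplotype_seq(pool, ind, copy, contig)[pos] == alt_idx
                for ind in range(3)
                for copy in range(2)
            )
            assert n_alt == site[f"alt_count_{pool}"]

    def test_truth_tsv_positions_are_one_based(self, tmp_path):
        truth = self._truth(RegimeMix(), seed=6)
        out = tmp_path / "truth.tsv"
        truth.to_tsv(out)
        loaded = pd.read_csv(out, sep="\t")
        assert (loaded["position"] == truth.sites["position"] + 1).all()


class TestSimulatePooledReads:
    def test_error_free_reads_match_source_haplotype(self, small_truth, small_errorfree_reads):
        for pool in POOLS:
            for read in small_errorfree_reads[pool][:200]:
                origin = parse_read_origin(read.id)
                hap = small_truth.haplotype_seq(
                    pool, origin["individual"], origin["copy"], origin["contig"]
                )
                seg = hap[origin["start"] : origin["start"] + len(read)]
                assert (encode_seq(read.seq) == seg).all()

    def test_total_bases_match_depth(self):
        ref = generate_reference(1, 10_000.0, 0.0, seed=3)
        model = PopulationModel(variable_site_density=0.001, seed=4)
        truth = simulate_pool_genotypes(model, ref)
        seqmodel = SequencingModel(mean_depth_per_pool=30.0, seed=5)
        reads = simulate_pooled_reads(truth, seqmodel)
        for pool in POOLS:
            total = sum(len(r) for r in reads[pool])
            assert abs(total - 30 * 10_000) / (30 * 10_000) < 0.10

    def test_deterministic_under_fixed_seed(self, small_truth):
        seqmodel = SequencingModel(mean_depth_per_pool=5.0, seed=21)
        a = simulate_pooled_reads(small_truth, seqmodel)
        b = simulate_pooled_reads(small_truth, seqmodel)
        for pool in POOLS:
            assert [(r.id, r.seq, r.qual.tolist()) for r in a[pool]] == [
                (r.id, r.seq, r.qual.tolist()) for r in b[pool]
            ]

    def test_origin_tags_name_existing_haplotypes(self, small_truth, small_reads):
        n = small_truth.n_individuals_per_pool
        for pool in POOLS:
            for read in small_reads[pool][:100]:
                origin = parse_read_origin(read.id)
                assert origin["pool"] == pool
                assert origin["contig"] in small_truth.reference
                assert 0 <= origin["individual"] < n
                assert origin["copy"] in (0, 1)

    def test_alt_read_fraction_tracks_pool_frequency(self):
        # sites at realized frequency 0.5: aggregate alt fraction ~ Binomial(depth, 0.5)
        ref = generate_reference(1, 50_000.0, 0.0, seed=8)
        model = PopulationModel(
            variable_site_density=0.02, allele_freq_spec=lambda rng: (0.5, 0.5), seed=9
        )
        truth = simulate_pool_genotypes(model, ref)
        sites = truth.sites[truth.sites["alt_count_high"] == 3]
        assert len(sites) > 300
        seqmodel = SequencingModel(
            mean_depth_per_pool=30.0, substitution_error_rate=0.0, seed=10
        )
        reads = simulate_pooled_reads(truth, seqmodel)
        alt_frac = []
        depths = []
        cover = {}
        for read in reads["high"]:
            origin = parse_read_origin(read.id)
            cover.setdefault((origin["start"], origin["start"] + len(read)), []).append(read)
        arr_sites = sites[["position"]].to_numpy().ravel()
        alt_bases = sites["alt_allele"].to_numpy()
        counts = np.zeros(len(arr_sites))
        totals = np.zeros(len(arr_sites))
        for (start, end), rds in cover.items():
            mask = (arr_sites >= start) & (arr_sites < end)
            for si in np.flatnonzero(mask):
                pos = arr_sites[si]
                for read in rds:
                    totals[si] += 1
                    if read.seq[pos - start] == alt_bases[si]:
                        counts[si] += 1
        ok = totals > 0
        frac = counts[ok].sum() / totals[ok].sum()
        # overall alt fraction should be 0.5 within binomial error
        se = 0.5 / np.sqrt(totals[ok].sum())
        assert abs(frac - 0.5) < 4 * se
        # and per-site variance consistent with binomial at the observed depths
        mean_depth = totals[ok].mean()
        assert mean_depth > 15

    def test_empty_truth_rejected(self):
        seqmodel = SequencingModel(seed=1)
        bad = type("T", (), {"sites": None, "reference": {}})()
        with pytest.raises((ValueError, AttributeError)):
            simulate_pooled_reads(bad, seqmodel)


class TestGenotypePanel:
    def test_complete_inbreeding_has_no_heterozygotes(self):
        panel = simulate_genotype_panel(p=0.5, n=500, inbreeding_f=1.0, seed=3)
        assert (panel["genotype"] != 1).all()

    def test_hwe_heterozygote_fraction(self):
        panel = simulate_genotype_panel(p=0.5, n=10_000, inbreeding_f=0.0, seed=4)
        frac = (panel["genotype"] == 1).mean()
        se = np.sqrt(0.5 * 0.5 / 10_000)
        assert abs(frac - 0.5) < 3 * se

    def test_monomorphic_edges(self):
        all_alt = simulate_genotype_panel(p=0.0, n=50, seed=5)
        assert (all_alt["genotype"] == 2).all()
        all_ref = simulate_genotype_panel(p=1.0, n=50, seed=6)
        assert (all_ref["genotype"] == 0).all()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_genotype_panel(p=1.5, n=10)
        with pytest.raises(ValueError):
            simulate_genotype_panel(p=0.5, n=0)
        with pytest.raises(ValueError):
            simulate_genotype_panel(p=0.5, n=10, inbreeding_f=2.0)
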
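"""Pooled SNP calling, cross-pool classification, divergence, Ts/Tv, panel."""

import numpy as np
import pandas as pd
import pytest

from pikapool.mapping import PoolPileup
from pikapool.reads import MAX_PHRED
from pikapool.snps import (
    CallingPolicy,
    call_group_snps,
    category_counts,
    divergence_index,
    merge_and_classify,
    select_candidate_panel,
    transition_transversion,
    write_vcf,
)

BASE = {"A": 0, "C": 1, "G": 2, "T": 3}


def pileup_from_columns(columns, length=400, contig="ctg1"):
    """Build a pileup directly from {(pool, pos): [(base, qual, count), ...]}."""
    pileup = PoolPileup({contig: "A" * length})
    arr = pileup.counts(contig)
    for (pool, pos), entries in columns.items():
        pi = pileup.pool_index[pool]
        for base, qual, count in entries:
            arr[pi, pos, BASE[base], qual] += count
    return pileup


POLICY = CallingPolicy()  # 8x / 10% / 2 reads / Q20


class TestCallGroupSnps:
    @pytest.mark.parametrize(
        "entries,expect_call",
        [
            # all four thresholds met: depth 10, A 8 + G 2 at Q30
            ([("A", 30, 8), ("G", 30, 2)], True),
            # depth 7 < 8: no call
            ([("A", 30, 5), ("G", 30, 2)], False),
            # single variant read < 2 per allele: no call
            ([("A", 30, 9), ("G", 30, 1)], False),
            # variant reads below Q20: no call
            ([("A", 30, 18), ("G", 10, 2)], False),
            # variant below 10% frequency: no call
            ([("A", 30, 28), ("G", 30, 2)], False),
        ],
    )
    def test_threshold_examples(self, entries, expect_call):
        pileup = pileup_from_columns({("high", 50): entries})
        calls = call_group_snps(pileup, "high", POLICY)
        assert (len(calls) == 1) == expect_call

    def test_reported_frequencies_sum_to_one(self):
        pileup = pileup_from_columns({("high", 10): [("A", 30, 8), ("G", 30, 2)]})
        calls = call_group_snps(pileup, "high", POLICY)
        freqs = [float(f) for f in calls.iloc[0]["freqs"].split(",")]
        assert sum(freqs) == pytest.approx(1.0)
        assert freqs == pytest.approx([0.8, 0.2])

    def test_quality_failing_reads_excluded_from_depth(self):
        # 6 good + 5 bad reads: quality-passing depth 6 < 8 -> no call
        pileup = pileup_from_columns(
            {("high", 5): [("A", 30, 4), ("G", 30, 2), ("C", 10, 5)]}
        )
        assert len(call_group_snps(pileup, "high", POLICY)) == 0

    def test_brute_force_oracle_agreement(self):
        # exact agreement with a per-column re-check on random columns
        rng = np.random.default_rng(7)
        pileup = PoolPileup({"ctg1": "A" * 2000})
        arr = pileup.counts("ctg1")
        for pos in range(2000):
            for _ in range(int(rng.integers(0, 4))):
                arr[0, pos, rng.integers(4), rng.integers(0, MAX_PHRED + 1)] += int(
                    rng.integers(1, 8)
                )
        calls = call_group_snps(pileup, "high", POLICY)
        called = {int(r.position) for r in calls.itertuples()}
        for pos in range(2000):
            qpass = arr[0, pos, :, POLICY.min_base_quality :].sum(axis=-1)
            depth = int(qpass.sum())
            passing = [
                c
                for c in qpass
                if c >= POLICY.min_reads_per_allele
                and depth > 0
                and c / depth >= POLICY.min_variant_freq
            ]
            expect = depth >= POLICY.min_coverage and len(passing) >= 2
            assert (pos in called) == expect, pos


class TestMergeAndClassify:
    def _merge(self, columns):
        pileup = pileup_from_columns(columns)
        calls = {p: call_group_snps(pileup, p, POLICY) for p in ("high", "low")}
        return merge_and_classify(calls["high"], calls["low"], pileup, POLICY)

    def test_polymorphic_in_both_pools_is_category_a(self):
        merged = self._merge(
            {
                ("high", 40): [("A", 30, 6), ("G", 30, 4)],
                ("low", 40): [("A", 30, 7), ("G", 30, 3)],
            }
        )
        assert merged.iloc[0]["category"] == "a"

    def test_fixed_in_one_pool_is_category_b(self):
        merged = self._merge(
            {
                ("high", 40): [("A", 30, 6), ("G", 30, 4)],
                ("low", 40): [("A", 30, 12)],
            }
        )
        assert merged.iloc[0]["category"] == "b"

    def test_fixed_different_is_category_c_with_unit_divergence(self):
        merged = self._merge(
            {
                ("high", 40): [("G", 30, 15)],
                ("low", 40): [("A", 30, 20)],
            }
        )
        row = merged.iloc[0]
        assert row["category"] == "c"
        assert row["divergence"] == 1.0

    def test_low_coverage_other_pool_is_undetermined(self):
        merged = self._merge(
            {
                ("high", 40): [("A", 30, 6), ("G", 30, 4)],
                ("low", 40): [("A", 30, 5)],
            }
        )
        row = merged.iloc[0]
        assert row["status"] == "undetermined"
        assert row["category"] == ""

    def test_partition_identity(self, benchmark_result):
        cats = category_counts(benchmark_result.merged)
        assert cats["a"] + cats["b"] + cats["c"] + cats["undetermined"] == cats["total"]

    def test_category_c_always_has_unit_divergence(self, benchmark_result):
        merged = benchmark_result.merged
        det = merged[merged["status"] == "determined"]
        c_sites = det[det["category"] == "c"]
        assert len(c_sites) > 0
        assert (c_sites["divergence"] == 1.0).all()
        biallelic = det[det["subst_class"] != "multiallelic"]
        non_c = biallelic[biallelic["category"] != "c"]
        assert (non_c["divergence"] < 1.0).all()
        assert biallelic["divergence"].between(0, 1).all()


class TestDivergenceIndex:
    def test_arithmetic(self):
        rec = {
            "status": "determined",
            "alleles": "A,G",
            "f_high_major": 0.9,
            "f_low_major": 0.6,
        }
        assert divergence_index(rec) == pytest.approx(0.30)

    def test_equal_frequencies_give_zero(self):
        rec = {
            "status": "determined",
            "alleles": "A,G",
            "f_high_major": 0.5,
            "f_low_major": 0.5,
        }
        assert divergence_index(rec) == 0.0

    def test_undetermined_rejected(self):
        with pytest.raises(ValueError):
            divergence_index(
                {"status": "undetermined", "alleles": "A,G",
                 "f_high_major": 1.0, "f_low_major": 0.0}
            )

    def test_multiallelic_rejected(self):
        with pytest.raises(ValueError):
            divergence_index(
                {"status": "determined", "alleles": "A,C,G",
                 "f_high_major": 1.0, "f_low_major": 0.0}
            )


class TestTsTv:
    def _records(self, pairs):
        return pd.DataFrame(
            {
                "subst_class": [
                    "transition" if frozenset(p) in ({"A", "G"}, {"C", "T"})
                    else "transversion"
                    for p in pairs
                ]
            }
        )

    def test_classification_and_ratio(self):
        records = self._records([("A", "G"), ("C", "T"), ("A", "C")])
        classes, ratio = transition_transversion(records)
        assert list(classes) == ["transition", "transition", "transversion"]
        assert ratio == pytest.approx(2.0)

    def test_no_transversions_flags_undefined(self):
        _, ratio = transition_transversion(self._records([("A", "G")]))
        assert np.isnan(ratio)


class TestPanelSelection:
    def _frame(self, rows):
        base = {
            "contig": "ctg1", "status": "determined", "category": "a",
            "alleles": "A,G", "major_allele": "A", "f_high_major": 1.0,
            "f_low_major": 0.4, "subst_class": "transition",
            "depth_high": 20, "depth_low": 20,
        }
        return pd.DataFrame([{**base, **r} for r in rows])

    def test_selection_rules(self):
        records = self._frame(
            [
                {"position": 200, "divergence": 0.62},  # selected
                {"position": 600, "divergence": 0.45},  # below threshold
                {"position": 1000, "divergence": 0.80},  # neighbour 40 bases away
                {"position": 1040, "divergence": 0.10},
                {"position": 1960, "divergence": 0.90},  # window exceeds contig
            ]
        )
        out = select_candidate_panel(records, {"ctg1": 2000})
        assert out["position"].tolist() == [200]

    def test_window_is_centred_and_inside_contig(self):
        records = self._frame([{"position": 500, "divergence": 0.7}])
        out = select_candidate_panel(records, {"ctg1": 2000}, amplicon_length=200)
        row = out.iloc[0]
        assert (row["window_start"], row["window_end"]) == (400, 600)


class TestVcfExport:
    def test_biallelic_records_written(self, tmp_path):
        ref = {"ctg1": "A" * 400}
        pileup = pileup_from_columns(
            {("high", 40): [("G", 30, 15)], ("low", 40): [("C", 30, 20)]}
        )
        calls = {p: call_group_snps(pileup, p, POLICY) for p in ("high", "low")}
        merged = merge_and_classify(calls["high"], calls["low"], pileup, POLICY)
        out = tmp_path / "out.vcf"
        write_vcf(merged, ref, out)
        lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 1
        fields = lines[0].split("\t")
        assert fields[0] == "ctg1" and fields[1] == "41"
        assert "CAT=c" in fields[7] and "D=1.0000" in fields[7]
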
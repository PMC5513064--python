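"""Generator truth records, determinism, and degenerate-input contracts."""

import numpy as np
import pytest

from ribodevtyper import io as rio
from ribodevtyper import sticky
from ribodevtyper.synthetic import make_genome, make_type_pair, make_utr_set, simulate_reads


def diff_positions(a: str, b: str) -> list[int]:
    assert len(a) == len(b)
    return [i + 1 for i, (x, y) in enumerate(zip(a, b)) if x != y]


class TestMakeTypePair:
    def test_identity_case(self):
        pair = make_type_pair(300, [("A", 1, 300)], {"A": 0.0}, seed=1)
        assert pair.maternal_seq == pair.somatic_seq
        assert pair.planted_variants == []

    def test_forced_substitution_count(self):
        pair = make_type_pair(100, [("A", 1, 100)], {"A": 0.03}, n_pairs=0, seed=2)
        assert len(pair.planted_variants) == 3
        assert all(v.kind == "substitution" for v in pair.planted_variants)

    def test_truth_equals_bruteforce_diff(self):
        # substitution-only pair: the truth list must equal the position-by-
        # position diff of the two emitted strings
        pair = make_type_pair(
            1900,
            [("A", 1, 1400), ("5'", 1401, 1900)],
            {"A": 0.029, "5'": 0.103},
            n_pairs=0,
            seed=3,
        )
        expected = diff_positions(pair.somatic_seq, pair.maternal_seq)
        assert sorted(v.somatic_pos for v in pair.planted_variants) == expected
        for v in pair.planted_variants:
            assert pair.somatic_seq[v.somatic_pos - 1] == v.somatic_bases
            assert pair.maternal_seq[v.maternal_pos - 1] == v.maternal_bases

    def test_per_domain_truth_counts(self):
        pair = make_type_pair(
            1900,
            [("A", 1, 1400), ("5'", 1401, 1900)],
            {"A": 0.029, "5'": 0.103},
            n_pairs=0,
            seed=4,
        )
        by_domain = {"A": 0, "5'": 0}
        for v in pair.planted_variants:
            by_domain[v.domain_name] += 1
        assert by_domain == {"A": round(0.029 * 1400), "5'": round(0.103 * 500)}

    def test_every_variant_inside_exactly_one_domain(self, small_pair):
        for v in small_pair.planted_variants:
            owners = [
                name
                for name, s, e in small_pair.domain_spec
                if s <= max(v.somatic_pos, 1) <= e
            ]
            assert len(owners) == 1

    def test_covariations_are_legal_pairs_in_both_types(self, small_pair):
        wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
        assert small_pair.covariation_positions
        for i, j in small_pair.covariation_positions:
            assert (i, j) in small_pair.pairing_map
            s_pair = (small_pair.somatic_seq[i - 1], small_pair.somatic_seq[j - 1])
            subs = {
                v.somatic_pos: v.maternal_bases
                for v in small_pair.planted_variants
                if v.kind == "substitution"
            }
            m_pair = (subs[i], subs[j])
            assert s_pair in wc and m_pair in wc and s_pair != m_pair

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"outside \[0, 1\]"):
            make_type_pair(100, [("A", 1, 100)], {"A": 1.5}, seed=0)

    def test_too_many_covariations_rejected(self):
        with pytest.raises(ValueError, match="exceeds available pairs"):
            make_type_pair(
                100, [("A", 1, 100)], {"A": 0.0}, n_covariations=5, n_pairs=2, seed=0
            )

    def test_non_tiling_domains_rejected(self):
        with pytest.raises(ValueError, match="tile"):
            make_type_pair(100, [("A", 1, 50), ("B", 60, 100)], {}, seed=0)

    def test_seed_reproducibility(self):
        kwargs = dict(
            base_length=400,
            domain_spec=[("A", 1, 400)],
            per_domain_rates={"A": 0.05},
            n_covariations=1,
            seed=99,
        )
        a, b = make_type_pair(**kwargs), make_type_pair(**kwargs)
        assert a.maternal_seq == b.maternal_seq
        assert a.somatic_seq == b.somatic_seq
        assert a.pairing_map == b.pairing_map


class TestMakeGenome:
    def test_intended_completeness_rules(self, curated_pairs):
        truth = make_genome(
            curated_pairs,
            units_per_type={"maternal": 0, "somatic": 3},
            partial_spec=[(1, "5.8S", 100), (2, "18S", 500), (2, "28S", 500)],
            seed=5,
        )
        calls = [u.intended_completeness for u in truth.units]
        assert calls == ["Complete", "Partial", "dropped"]

    def test_truncation_above_threshold_stays_complete(self, curated_pairs):
        truth = make_genome(
            curated_pairs,
            units_per_type={"maternal": 1, "somatic": 0},
            partial_spec=[(0, "28S", 4100)],
            seed=6,
        )
        assert truth.units[0].intended_completeness == "Complete"

    def test_truncation_below_one_nt_rejected(self, curated_pairs):
        with pytest.raises(ValueError, match="below 1 nt"):
            make_genome(curated_pairs, partial_spec=[(0, "5.8S", 0)], seed=0)

    def test_element_intervals_carry_planted_sequence(self, curated_pairs):
        truth = make_genome(
            curated_pairs, units_per_type={"maternal": 1, "somatic": 1}, seed=7
        )
        contig = truth.genome[truth.contig_id]
        for unit in truth.units:
            for element, (start, end) in unit.element_intervals.items():
                expected = curated_pairs[element].seq_of(unit.type_label)
                assert contig[start - 1 : end] == expected

    def test_byte_identical_outputs_for_one_seed(self, curated_pairs, tmp_path):
        for name in ("a", "b"):
            truth = make_genome(curated_pairs, units_per_type=1, seed=11)
            rio.write_fasta(truth.genome, tmp_path / f"{name}.fasta")
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()


class TestSimulateReads:
    def test_pure_maternal_error_free_reads_are_substrings(self, small_pair):
        reads, truth = simulate_reads(small_pair, 1.0, 200, (30, 80), 0.0, seed=8)
        assert all(origin == "maternal" for origin in truth.per_read_origin)
        assert all(seq in small_pair.maternal_seq for _, seq in reads)

    def test_origin_counts_match_truth(self, small_pair):
        reads, truth = simulate_reads(small_pair, 0.3, 1000, (30, 80), 0.0, seed=9)
        n_maternal = sum(1 for o in truth.per_read_origin if o == "maternal")
        assert n_maternal == sum(1 for rid, _ in reads if rid.endswith("maternal"))
        # binomial draw at the requested fraction: within 4 SD of the mean
        assert abs(n_maternal - 300) < 4 * np.sqrt(1000 * 0.3 * 0.7)

    def test_error_rate_perturbs_reads(self, small_pair):
        reads, _ = simulate_reads(small_pair, 1.0, 100, (60, 60), 0.2, seed=10)
        assert any(seq not in small_pair.maternal_seq for _, seq in reads)

    @pytest.mark.parametrize(
        "kwargs, message",
        [
            (dict(maternal_fraction=0.5, n_reads=0), "positive"),
            (dict(maternal_fraction=1.5, n_reads=10), r"\[0, 1\]"),
            (
                dict(maternal_fraction=0.5, n_reads=10, read_length_range=(30, 10_000)),
                "read_length_range",
            ),
        ],
    )
    def test_invalid_parameters_rejected(self, small_pair, kwargs, message):
        with pytest.raises(ValueError, match=message):
            simulate_reads(small_pair, seed=0, **kwargs)

    def test_fastq_round_trip(self, small_pair, tmp_path):
        reads, _ = simulate_reads(small_pair, 0.5, 50, (30, 60), 0.0, seed=12)
        path = tmp_path / "reads.fastq"
        rio.write_fastq(reads, path)
        assert list(rio.read_fastq(path)) == reads


class TestMakeUtrSet:
    STRETCH_M = "ACGTACGGTTACAGCTAGGCAT"
    STRETCH_S = "TTGCAGCCATAGGATCCAA"

    def test_label_balance_is_exact(self):
        _, _, labels, _ = make_utr_set(
            201, 0.5, self.STRETCH_M, self.STRETCH_S, seed=13
        )
        assert sum(1 for v in labels.values() if v == "yes") == round(201 * 0.5)

    def test_planted_matches_are_recoverable_by_bruteforce(self):
        utrs, _, _, truth = make_utr_set(
            30, 0.5, self.STRETCH_M, self.STRETCH_S, (8, 12), seed=14
        )
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        stretches = {"maternal": self.STRETCH_M, "somatic": self.STRETCH_S}
        for tx, target, length, utr_pos, stretch_start in truth.planted_matches:
            planted = utrs[tx][utr_pos - 1 : utr_pos - 1 + length]
            source = stretches[target][stretch_start - 1 : stretch_start - 1 + length]
            assert planted == "".join(comp[c] for c in reversed(source))

    def test_empty_gene_set_is_not_an_error(self):
        utrs, tx2gene, labels, truth = make_utr_set(
            0, 0.5, self.STRETCH_M, self.STRETCH_S, seed=15
        )
        assert utrs == {} and tx2gene == {} and labels == {} and truth.genes == []

    def test_planted_length_below_five_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            make_utr_set(5, 0.5, self.STRETCH_M, self.STRETCH_S, (3, 8), seed=0)

    def test_stretch_shorter_than_planted_length_rejected(self):
        with pytest.raises(ValueError, match="stretch shorter"):
            make_utr_set(5, 0.5, "ACGTACG", self.STRETCH_S, (8, 10), seed=0)

    def test_forced_bias_with_clean_background_separates_classes(self):
        # maternal genes always target the maternal stretch and no chance
        # background matches exist: every maternal gene must come out gt1
        utrs, tx2gene, labels, _ = make_utr_set(
            12,
            0.5,
            self.STRETCH_M,
            self.STRETCH_S,
            (12, 12),
            affinity_bias={"maternal": 1.0, "not": 0.0},
            seed=16,
            clean_background=True,
        )
        counts = [
            sticky.stickiness(
                seq, self.STRETCH_M, self.STRETCH_S,
                transcript_id=tx, gene_id=tx2gene[tx],
            )
            for tx, seq in utrs.items()
        ]
        for ratio in sticky.gene_ms_ratios(counts, tx2gene):
            if labels[ratio.gene_id] == "yes":
                assert ratio.ratio_class == "gt1"
            else:
                assert ratio.ratio_class in ("lt1", "undefined")

    def test_seed_reproducibility(self):
        a = make_utr_set(20, 0.5, self.STRETCH_M, self.STRETCH_S, seed=17)
        b = make_utr_set(20, 0.5, self.STRETCH_M, self.STRETCH_S, seed=17)
        assert a[0] == b[0] and a[1] == b[1] and a[2] == b[2]


def test_genome_truth_self_consistency(curated_pairs):
    """Every planted unit is recoverable by scanning the emitted contig."""
    truth = make_genome(curated_pairs, units_per_type=1, seed=18)
    contig = truth.genome[truth.contig_id]
    for unit in truth.units:
        for element, (start, end) in unit.element_intervals.items():
            segment = contig[start - 1 : end]
            expected = curated_pairs[element].seq_of(unit.type_label)
            assert contig.count(segment) >= 1
            assert segment == expected
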
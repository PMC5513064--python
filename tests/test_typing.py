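"""Marker selection, read scanning, and the alignment typing contract."""

import numpy as np
import pytest

from ribodevtyper import synthetic
from ribodevtyper._seq import revcomp
from ribodevtyper.align import ReadScoreParams, align_read
from ribodevtyper.read_typing import (
    build_marker_index,
    scan_reads,
    select_markers,
    type_profile,
)

from _oracles import brute_force_markers, semiglobal_read_score

K = 26


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestSelectMarkers:
    def test_single_difference_yields_kmers_covering_it(self):
        rng = np.random.default_rng(0)
        somatic = random_seq(rng, 200)
        p = 100  # 1-based
        old = somatic[p - 1]
        maternal = somatic[: p - 1] + next(b for b in "ACGT" if b != old) + somatic[p:]
        markers = select_markers({"maternal": maternal, "somatic": somatic}, k=K)
        maternal_markers = [m for m in markers if m.type_label == "maternal"]
        assert 1 <= len(maternal_markers) <= K
        for m in maternal_markers:  # every marker window covers the variant
            assert m.position <= p <= m.position + K - 1
            assert m.sequence in maternal
            assert m.sequence not in somatic and revcomp(m.sequence) not in somatic

    def test_identical_references_yield_empty_list(self):
        seq = random_seq(np.random.default_rng(1), 300)
        assert select_markers({"maternal": seq, "somatic": seq}, k=K) == []

    def test_matches_bruteforce_enumeration(self, small_pair):
        refs = {"maternal": small_pair.maternal_seq, "somatic": small_pair.somatic_seq}
        markers = select_markers(refs, k=K)
        expected = brute_force_markers(refs, k=K)
        for label in refs:
            got = {m.sequence for m in markers if m.type_label == label}
            want = expected[label]
            # dedup folds a k-mer and its reverse complement together
            assert {min(s, revcomp(s)) for s in got} == {
                min(s, revcomp(s)) for s in want
            }

    def test_three_way_references_stay_mutually_specific(self, small_pair):
        rng = np.random.default_rng(2)
        refs = {
            "maternal": small_pair.maternal_seq,
            "somatic": small_pair.somatic_seq,
            "undetermined": random_seq(rng, 400),
        }
        for m in select_markers(refs, k=K):
            for label, seq in refs.items():
                if label == m.type_label:
                    continue
                assert m.sequence not in seq and revcomp(m.sequence) not in seq

    def test_fewer_than_two_references_rejected(self):
        with pytest.raises(ValueError, match="two type references"):
            select_markers({"maternal": "ACGT" * 20}, k=K)


class TestScanReads:
    def test_pure_somatic_reads_give_zero_maternal(self, small_pair):
        reads, _ = synthetic.simulate_reads(small_pair, 0.0, 500, (30, 80), 0.0, seed=3)
        markers = select_markers(
            {"maternal": small_pair.maternal_seq, "somatic": small_pair.somatic_seq}, k=K
        )
        profile = scan_reads(reads, markers, min_read_length=25, k=K)
        assert profile.counts["maternal"] == 0
        assert profile.percent_somatic == 100.0

    def test_short_reads_excluded_from_every_bucket(self, small_pair):
        markers = select_markers(
            {"maternal": small_pair.maternal_seq, "somatic": small_pair.somatic_seq}, k=K
        )
        reads = [("r1", small_pair.maternal_seq[:40]), ("r2", "ACGT")]
        profile = scan_reads(reads, markers, min_read_length=30, k=K)
        assert profile.total_scanned == 1

    def test_counts_sum_to_passing_reads(self, small_pair):
        reads, _ = synthetic.simulate_reads(small_pair, 0.5, 400, (30, 80), 0.02, seed=4)
        markers = select_markers(
            {"maternal": small_pair.maternal_seq, "somatic": small_pair.somatic_seq}, k=K
        )
        profile = scan_reads(reads, markers, min_read_length=30, k=K)
        n_passing = sum(1 for _, s in reads if len(s) >= 30)
        assert profile.total_scanned == n_passing

    def test_estimate_within_three_binomial_se(self, small_pair):
        reads, truth = synthetic.simulate_reads(small_pair, 0.8, 2000, (30, 80), 0.0, seed=5)
        markers = select_markers(
            {"maternal": small_pair.maternal_seq, "somatic": small_pair.somatic_seq}, k=K
        )
        profile = scan_reads(reads, markers, min_read_length=25, k=K)
        realized = truth.per_read_origin.count("maternal") / truth.n_reads
        assigned = profile.counts["maternal"] + profile.counts["somatic"]
        se = 100 * np.sqrt(realized * (1 - realized) / assigned)
        assert abs(profile.percent_maternal - 100 * realized) <= 3 * se

    def test_orientation_invariance(self, small_pair):
        reads, _ = synthetic.simulate_reads(small_pair, 0.5, 300, (30, 80), 0.0, seed=6)
        markers = select_markers(
            {"maternal": small_pair.maternal_seq, "somatic": small_pair.somatic_seq}, k=K
        )
        fwd = scan_reads(reads, markers, min_read_length=25, k=K)
        rev = scan_reads(
            [(rid, revcomp(seq)) for rid, seq in reads], markers, min_read_length=25, k=K
        )
        assert fwd.counts == rev.counts

    def test_garbage_reads_fall_in_unassigned_without_crash(self, small_pair):
        reads, _ = synthetic.simulate_reads(small_pair, 0.5, 100, (30, 30), 0.5, seed=7)
        markers = select_markers(
            {"maternal": small_pair.maternal_seq, "somatic": small_pair.somatic_seq}, k=K
        )
        profile = scan_reads(reads, markers, min_read_length=25, k=K)
        assert profile.counts["unassigned"] > 0

    def test_malformed_fastq_reports_record_index(self, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGTACGT\n+\nII\n")
        with pytest.raises(ValueError, match="index 1"):
            list(scan_reads(path, {}, min_read_length=1).counts)


class TestAlignRead:
    def test_exact_substring_scores_zero_and_is_accepted(self):
        rng = np.random.default_rng(8)
        ref = random_seq(rng, 300)
        score, accepted = align_read(ref[50:150], ref)
        assert score == 0.0 and accepted

    def test_five_percent_mismatch_boundary(self):
        rng = np.random.default_rng(9)
        ref = random_seq(rng, 400)
        read = list(ref[100:200])
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for i in (3, 17, 33, 48, 61):
            read[i] = flip[read[i]]
        score5, ok5 = align_read("".join(read), ref)
        assert (score5, ok5) == (-30.0, True)
        read[77] = flip[read[77]]
        score6, ok6 = align_read("".join(read), ref)
        assert (score6, ok6) == (-36.0, False)

    def test_ambiguous_bases_are_free(self):
        rng = np.random.default_rng(10)
        ref = random_seq(rng, 200)
        read = ref[40:90][:20] + "N" + ref[40:90][21:]
        score, accepted = align_read(read, ref)
        assert score == 0.0 and accepted

    def test_scores_match_dp_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            ref = random_seq(rng, int(rng.integers(60, 200)))
            n = int(rng.integers(10, 50))
            start = int(rng.integers(0, len(ref) - n))
            read = list(ref[start : start + n])
            for _ in range(int(rng.integers(0, 5))):  # substitutions
                i = int(rng.integers(0, n))
                read[i] = "ACGT"[int(rng.integers(0, 4))]
            if rng.random() < 0.4 and n > 12:  # deletion in the read
                i = int(rng.integers(1, n - 4))
                del read[i : i + int(rng.integers(1, 4))]
            read = "".join(read)
            score, _ = align_read(read, ref)
            assert score == semiglobal_read_score(read, ref)

    def test_empty_read_rejected(self):
        with pytest.raises(ValueError, match="length >= 1"):
            align_read("", "ACGT")


class TestTypeProfile:
    def test_pure_maternal_exact_reads_are_100_percent(self, curated_pairs):
        p58 = curated_pairs["5.8S"]
        reads, _ = synthetic.simulate_reads(p58, 1.0, 100, (110, 155), 0.0, seed=12)
        profile = type_profile(reads, p58.maternal_seq, p58.somatic_seq, min_read_length=100)
        assert profile.percent_maternal == 100.0

    def test_egg_vs_adult_contrast(self, curated_pairs):
        p58 = curated_pairs["5.8S"]
        for fraction, expect in ((1.0, 100.0), (0.0, 0.0)):
            reads, _ = synthetic.simulate_reads(p58, fraction, 150, (110, 155), 0.002, seed=13)
            profile = type_profile(reads, p58.maternal_seq, p58.somatic_seq, min_read_length=100)
            assert profile.percent_maternal == pytest.approx(expect, abs=2.0)

    def test_percent_somatic_monotone_in_truth_fraction(self, curated_pairs):
        p58 = curated_pairs["5.8S"]
        estimates = []
        for i, fraction in enumerate((0.0, 0.25, 0.5, 0.75, 1.0)):
            reads, _ = synthetic.simulate_reads(
                p58, 1.0 - fraction, 200, (110, 155), 0.0, seed=14
            )
            profile = type_profile(
                reads, p58.maternal_seq, p58.somatic_seq, min_read_length=100
            )
            estimates.append(profile.percent_somatic)
        assert estimates == sorted(estimates)

    def test_empty_fastq_flagged_undefined(self, curated_pairs):
        p58 = curated_pairs["5.8S"]
        profile = type_profile([], p58.maternal_seq, p58.somatic_seq)
        assert profile.total_scanned == 0
        assert profile.percent_maternal is None and profile.percent_somatic is None

    def test_orientation_invariance(self, curated_pairs):
        p58 = curated_pairs["5.8S"]
        reads, _ = synthetic.simulate_reads(p58, 0.5, 80, (110, 155), 0.002, seed=15)
        fwd = type_profile(reads, p58.maternal_seq, p58.somatic_seq, min_read_length=100)
        rev = type_profile(
            [(rid, revcomp(seq)) for rid, seq in reads],
            p58.maternal_seq, p58.somatic_seq, min_read_length=100,
        )
        assert fwd.counts == rev.counts

    def test_percentages_sum_to_100_over_assigned(self, curated_pairs):
        p58 = curated_pairs["5.8S"]
        reads, _ = synthetic.simulate_reads(p58, 0.4, 120, (110, 155), 0.01, seed=16)
        profile = type_profile(reads, p58.maternal_seq, p58.somatic_seq, min_read_length=100)
        assert profile.percent_maternal + profile.percent_somatic == pytest.approx(100.0)


def test_marker_and_alignment_assignment_concordant(curated_pairs):
    """Error-free reads long enough to carry a marker: the two estimators agree."""
    p58 = curated_pairs["5.8S"]
    reads, _ = synthetic.simulate_reads(p58, 0.5, 300, (110, 155), 0.0, seed=17)
    markers = select_markers(
        {"maternal": p58.maternal_seq, "somatic": p58.somatic_seq}, k=K
    )
    index = build_marker_index(markers)
    agree = total = 0
    for rid, seq in reads:
        marker_call = scan_reads([(rid, seq)], index, min_read_length=100, k=K)
        align_call = type_profile(
            [(rid, seq)], p58.maternal_seq, p58.somatic_seq, min_read_length=100
        )
        m = [t for t in ("maternal", "somatic") if marker_call.counts[t]]
        a = [t for t in ("maternal", "somatic") if align_call.counts[t]]
        if m and a:
            total += 1
            agree += m == a
    assert total > 200
    assert agree / total >= 0.99
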
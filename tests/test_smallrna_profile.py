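"""Read preprocessing, mismatch-tolerant alignment, profiling and
classification of small-RNA signatures."""

import math

import numpy as np
import pytest

from evesurveyor import smallrna_profile as sp
from evesurveyor.eve_discovery import revcomp
from evesurveyor.smallrna_profile import (Alignment, AlignmentPolicy,
                                          ClassifierThresholds, ProfileClass,
                                          Read, ReadFilterConfig)


def _read(seq, q=40, rid="r"):
    return Read(rid, seq, [q] * len(seq))


# ---------------------------------------------------------------------------
# preprocessing

@pytest.mark.parametrize("read,reason", [
    (_read("ACGTACGTACGTAC"), "too_short"),            # 14 nt, high quality
    (_read("ACGTNACGTACGTACGTACGT"), "ambiguous"),     # one N
    (_read("ACGTACGTACGTACGTACGT", q=10), "low_quality"),
    (_read("A" * 40), "too_long"),
])
def test_filter_reasons_first_match_wins(read, reason):
    kept, stats = sp.preprocess_reads([read])
    assert kept == []
    assert getattr(stats, reason) == 1
    others = {"low_quality", "ambiguous", "too_short", "too_long"} - {reason}
    assert all(getattr(stats, o) == 0 for o in others)


def test_adapter_trimming_keeps_insert():
    adapter = "TGGAATTCTCGGGTGCCAAGG"
    insert = "ACGTACGTACGTACGTACGTACGTAC"  # 26 nt
    read = _read(insert + adapter)
    cfg = ReadFilterConfig(adapter_seq=adapter)
    kept, stats = sp.preprocess_reads([read], cfg)
    assert len(kept) == 1
    assert kept[0].seq == insert
    assert stats.adapter_trimmed == 1


def test_empty_input():
    kept, stats = sp.preprocess_reads([])
    assert kept == [] and stats.n_input == 0 and stats.n_kept == 0


def test_malformed_fastq_reports_record_index(tmp_path):
    p = tmp_path / "bad.fq"
    p.write_text("@r1\nACGTACGTACGTACGT\n+\nIIIIIIIIIIIIIIII\n"
                 "@r2\nACGTACGT\n+\nIII\n")
    with pytest.raises(ValueError, match="record 1"):
        sp.parse_fastq(p)


def test_phred64_like_qualities_rejected():
    bad = Read("r", "ACGTACGTACGTACGTACGT", [70] * 20)
    with pytest.raises(ValueError, match="Phred"):
        sp.preprocess_reads([bad])


def test_filter_config_validation():
    with pytest.raises(ValueError):
        ReadFilterConfig(min_length_nt=40, max_length_nt=35)


# ---------------------------------------------------------------------------
# alignment

def test_exact_substring_alignment():
    locus = "AAACCCGGGTTTACGTACGTGGCCAATT"
    read = _read(locus[5:25], rid="r1")
    alns = sp.align_reads([read], {"L": locus})
    assert len(alns) == 1
    a = alns[0]
    assert (a.offset, a.strand, a.n_mismatch, a.weight) == (6, "+", 0, 1.0)


def test_palindrome_aligns_both_strands_half_weight():
    pal = "GAATTC" * 4  # reverse complement of itself
    locus = "TTTTTT" + pal + "GGGGGG"
    read = _read(pal, rid="r1")
    alns = sp.align_reads([read], {"L": locus})
    assert len(alns) == 2
    assert {a.strand for a in alns} == {"+", "-"}
    assert all(a.weight == 0.5 for a in alns)


def test_all_best_keeps_minimal_mismatch_stratum():
    locus = "ACGTACGTACGTACGTACGT" + "T" * 10 + "ACGTACGTACGTACGAACGT"
    read = _read("ACGTACGTACGTACGTACGT")
    alns = sp.align_reads([read], {"L": locus},
                          AlignmentPolicy(max_mismatches=1))
    assert all(a.n_mismatch == 0 for a in alns)


def _brute_force_alignments(read_seq, locus, max_mm):
    hits = []
    for strand, seq in (("+", read_seq), ("-", revcomp(read_seq))):
        for off in range(len(locus) - len(seq) + 1):
            mm = sum(a != b for a, b in zip(seq, locus[off : off + len(seq)]))
            if mm <= max_mm:
                hits.append((off + 1, strand, mm))
    return sorted(hits)


def test_aligner_equals_brute_force_oracle():
    rng = np.random.default_rng(17)
    bases = np.array(list("ACGT"))
    for _ in range(30):
        locus = "".join(bases[rng.integers(0, 4, size=300)])
        read = "".join(bases[rng.integers(0, 4, size=int(rng.integers(15, 30)))])
        got = sorted(
            (a.offset, a.strand, a.n_mismatch)
            for a in sp.align_reads(
                [_read(read)], {"L": locus},
                AlignmentPolicy(max_mismatches=1, multimap_rule="ALL_BEST"))
        )
        expected = _brute_force_alignments(read, locus, 1)
        if expected:
            best = min(m for _, _, m in expected)
            expected = sorted(h for h in expected if h[2] == best)
        assert got == expected


# ---------------------------------------------------------------------------
# profile

def test_empty_profile_is_insufficient():
    prof = sp.compute_profile([], "L", 100)
    assert prof.n_aligned == 0
    cls, _ = sp.classify_profile(prof)
    assert cls is ProfileClass.INSUFFICIENT


def test_coverage_conservation_identity():
    alns = [
        Alignment("r1", "L", 1, "+", 0, 1.0, 20, "A" * 20),
        Alignment("r2", "L", 5, "+", 0, 0.5, 25, "A" * 25),
        Alignment("r3", "L", 30, "-", 1, 1.0, 22, "A" * 22),
    ]
    prof = sp.compute_profile(alns, "L", 100)
    assert prof.coverage_plus.sum() == pytest.approx(1.0 * 20 + 0.5 * 25)
    assert prof.coverage_minus.sum() == pytest.approx(1.0 * 22)
    hist_total = sum(prof.size_hist_plus.values()) + sum(prof.size_hist_minus.values())
    assert hist_total == pytest.approx(prof.n_aligned)


def test_five_prime_enrichment_extremes():
    alns = [Alignment(f"r{i}", "L", 1 + i % 10, "+", 0, 1.0, 26, "T" + "A" * 25)
            for i in range(200)]
    prof = sp.compute_profile(alns, "L", 100)
    u, p = sp.five_prime_enrichment_test(prof)
    assert u == 1.0 and p < 1e-6


def test_five_prime_sentinel_without_pirna_reads():
    alns = [Alignment("r", "L", 1, "+", 0, 1.0, 18, "A" * 18)]
    prof = sp.compute_profile(alns, "L", 100)
    u, p = sp.five_prime_enrichment_test(prof)
    assert math.isnan(u) and p == 1.0


def test_hotspot_detection_on_concentrated_coverage():
    alns = []
    # 200 reads piled on a 20 nt window of a 600 nt locus, 30 elsewhere
    for i in range(200):
        alns.append(Alignment(f"h{i}", "L", 300, "+", 0, 1.0, 20, "A" * 20))
    for i in range(30):
        alns.append(Alignment(f"b{i}", "L", 1 + (i * 19) % 550, "+", 0, 1.0,
                              20, "A" * 20))
    prof = sp.compute_profile(alns, "L", 600)
    assert any(s <= 300 <= e for s, e in prof.hotspots)


def test_classification_read_order_and_strand_invariance(planted_genome):
    """Class is unchanged by read order permutation and by locus
    reverse-complementation (strand labels swap)."""
    _, genome, _, truth = planted_genome
    from evesurveyor import synthetic_data as sd
    rec = truth.records[0]
    region = genome[rec.contig][rec.start - 1 : rec.end]
    spec = sd.SrnaProfileSpec.pirna_like("planted1", n_reads=400)
    records, _ = sd.simulate_small_rna(genome, truth, spec,
                                       np.random.default_rng(5))
    reads = [Read(r.id, str(r.seq), r.letter_annotations["phred_quality"])
             for r in records]

    def classify(reads_list, locus_seq):
        alns = sp.align_reads(reads_list, {"L": locus_seq})
        prof = sp.compute_profile(alns, "L", len(locus_seq))
        return sp.classify_profile(prof)[0], prof

    cls_ref, prof_ref = classify(reads, region)
    rng = np.random.default_rng(0)
    shuffled = [reads[i] for i in rng.permutation(len(reads))]
    cls_perm, _ = classify(shuffled, region)
    cls_rc, prof_rc = classify(reads, revcomp(region))
    assert cls_ref == cls_perm == cls_rc
    assert prof_rc.major_strand_fraction == pytest.approx(
        prof_ref.major_strand_fraction)
    assert sum(prof_rc.size_hist_minus.values()) == pytest.approx(
        sum(prof_ref.size_hist_plus.values()))


def test_simulated_profiles_classify_as_planted(planted_genome):
    """PIRNA_LIKE simulations classify PIRNA_TARGET; DEGRADATION simulations
    never do (a handful of seeds; the wider sweep runs in acceptance)."""
    _, genome, _, truth = planted_genome
    from evesurveyor import synthetic_data as sd
    rec = truth.records[0]
    region = genome[rec.contig][rec.start - 1 : rec.end]
    for seed in range(3):
        rng = np.random.default_rng(seed)
        for factory, expected in (
            (sd.SrnaProfileSpec.pirna_like, ProfileClass.PIRNA_TARGET),
            (sd.SrnaProfileSpec.degradation, ProfileClass.DEGRADATION),
        ):
            spec = factory("planted1")
            records, _ = sd.simulate_small_rna(genome, truth, spec, rng)
            reads = [Read(r.id, str(r.seq),
                          r.letter_annotations["phred_quality"])
                     for r in records]
            alns = sp.align_reads(reads, {"planted1": region})
            prof = sp.compute_profile(alns, "planted1", len(region))
            cls, rationale = sp.classify_profile(prof)
            assert cls is expected, (seed, rationale)


def test_threshold_validation():
    with pytest.raises(ValueError):
        ClassifierThresholds(pirna_len_lo=10)
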
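"""Naive aligner, hit counting and ChIP-vs-input enrichment."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from satrep.align import (
    HitCounts,
    count_hits_naive,
    count_hits_sam,
    count_mapped,
    enrichment,
    naive_align,
    write_sam,
)
from satrep.annotation import RepeatInstance
from satrep.repeat_genome import RepeatGenome, build_repeat_genome
from conftest import random_seq
from oracles import brute_force_align


def simple_rg(seed=3, lengths=(120, 80)):
    rng = np.random.default_rng(seed)
    seq, pos, inst = "", 0, []
    for ln in lengths:
        seq += random_seq(rng, 20)
        pos += 20
        inst.append(RepeatInstance("c", pos, pos + ln, "+", "fam"))
        seq += random_seq(rng, ln)
        pos += ln
    return build_repeat_genome({"c": seq}, inst), {"c": seq}


def test_exact_substring_maps_with_zero_mismatches():
    rg, _ = simple_rg()
    read = rg.segment_sequence(0)[40:76]
    res = naive_align(read, rg, 0)
    assert res.mapped and res.mismatches == 0 and res.offset == 40
    assert res.strand == "+"


def test_reverse_complement_read_maps():
    from satrep.repeat_genome import reverse_complement
    rg, _ = simple_rg()
    read = reverse_complement(rg.segment_sequence(1)[5:41])
    res = naive_align(read, rg, 0)
    assert res.mapped and res.strand == "-"


def test_boundary_spanning_read_blocked_by_spacer():
    """A read stitched across two instances cannot map: the NNNNN spacer
    guarantees >= 5 mismatches at the only candidate offsets."""
    rg, _ = simple_rg()
    a, b = rg.segment_sequence(0), rg.segment_sequence(1)
    read = a[-18:] + b[:18]
    assert not naive_align(read, rg, 3).mapped
    mapped, *_ = brute_force_align(read, rg.sequence, 4)
    assert not mapped


def test_mismatch_threshold_boundary():
    rg, _ = simple_rg()
    read = list(rg.segment_sequence(0)[10:46])
    read[5] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[5]]
    read = "".join(read)
    assert naive_align(read, rg, 1).mapped
    assert naive_align(read, rg, 1).mismatches == 1
    assert not naive_align(read, rg, 0).mapped


def test_n_in_read_counts_as_mismatch():
    rg, _ = simple_rg()
    read = "N" + rg.segment_sequence(0)[1:36]
    assert naive_align(read, rg, 0).mapped is False
    assert naive_align(read, rg, 1).mapped


def test_empty_and_oversized_reads_rejected():
    rg, _ = simple_rg()
    with pytest.raises(ValueError):
        naive_align("", rg, 1)
    with pytest.raises(ValueError):
        naive_align("A" * (len(rg.sequence) + 1), rg, 1)


@given(st.integers(0, 2 ** 31 - 1))
def test_naive_align_matches_brute_force(seed):
    """Vectorised aligner agrees with the literal per-offset scan,
    including offsets, mismatch counts and tie-breaking."""
    rng = np.random.default_rng(seed)
    ref = random_seq(rng, int(rng.integers(60, 400)))
    rg = RepeatGenome("f", ref)
    k = int(rng.integers(15, 40))
    if rng.random() < 0.7:  # planted read, sometimes mutated
        start = int(rng.integers(0, len(ref) - k + 1))
        read = list(ref[start:start + k])
        for _ in range(int(rng.integers(0, 4))):
            i = int(rng.integers(0, k))
            read[i] = "ACGT"[int(rng.integers(0, 4))]
        read = "".join(read)
    else:
        read = random_seq(rng, k)
    max_mm = int(rng.integers(0, 6))
    got = naive_align(read, rg, max_mm)
    exp = brute_force_align(read, ref, max_mm)
    assert (got.mapped, got.offset, got.mismatches, got.strand) == exp


def test_count_mapped_agrees_with_naive_align():
    rg, _ = simple_rg()
    rng = np.random.default_rng(5)
    reads = []
    for _ in range(60):
        if rng.random() < 0.5:
            s = int(rng.integers(0, len(rg.sequence) - 36))
            reads.append(rg.sequence[s:s + 36].replace("N", "A"))
        else:
            reads.append(random_seq(rng, 36))
    flags = count_mapped(reads, rg, 2)
    expected = [naive_align(r, rg, 2).mapped for r in reads]
    assert list(flags) == expected


def test_count_hits_sam_distinct_reads(tmp_path, major_rg):
    """4 reads mapped once + 1 read with 3 secondary records + 5 unmapped
    -> hits 5 of total 10."""
    import pysam
    path = tmp_path / "x.sam"
    header = {"HD": {"VN": "1.6"},
              "SQ": [{"SN": major_rg.family, "LN": len(major_rg.sequence)}]}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        def rec(name, flag, pos):
            r = pysam.AlignedSegment(out.header)
            r.query_name = name
            r.flag = flag
            if flag & 4:
                r.reference_id, r.reference_start = -1, -1
            else:
                r.reference_id, r.reference_start = 0, pos
                r.cigarstring = "36M"
            r.query_sequence = "A" * 36 if not flag & 0x100 else None
            return r
        for i in range(4):
            out.write(rec(f"m{i}", 0, 10 + i))
        out.write(rec("multi", 0, 50))
        for j in range(3):
            out.write(rec("multi", 0x100, 60 + j))
        for i in range(5):
            out.write(rec(f"u{i}", 4, 0))
    hc = count_hits_sam(path, major_rg.family)
    assert (hc.hits, hc.total_reads) == (5, 10)


def test_count_hits_sam_requires_total_when_no_unmapped(tmp_path, major_rg):
    import pysam
    path = tmp_path / "y.sam"
    header = {"HD": {"VN": "1.6"},
              "SQ": [{"SN": major_rg.family, "LN": len(major_rg.sequence)}]}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        r = pysam.AlignedSegment(out.header)
        r.query_name, r.flag = "a", 0
        r.reference_id, r.reference_start, r.cigarstring = 0, 0, "36M"
        r.query_sequence = "A" * 36
        out.write(r)
    with pytest.raises(ValueError, match="total_reads"):
        count_hits_sam(path, major_rg.family)
    hc = count_hits_sam(path, major_rg.family, total_reads=1000)
    assert (hc.hits, hc.total_reads) == (1, 1000)


def test_count_hits_sam_family_mismatch(tmp_path, major_rg):
    import pysam
    path = tmp_path / "z.sam"
    header = {"HD": {"VN": "1.6"},
              "SQ": [{"SN": major_rg.family, "LN": len(major_rg.sequence)}]}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        r = pysam.AlignedSegment(out.header)
        r.query_name, r.flag = "a", 0
        r.reference_id, r.reference_start, r.cigarstring = 0, 0, "36M"
        r.query_sequence = "A" * 36
        out.write(r)
    with pytest.raises(ValueError, match="does not match"):
        count_hits_sam(path, "other_family")


def test_empty_stream_with_declared_total(tmp_path, major_rg):
    import pysam
    path = tmp_path / "e.sam"
    header = {"HD": {"VN": "1.6"},
              "SQ": [{"SN": major_rg.family, "LN": len(major_rg.sequence)}]}
    with pysam.AlignmentFile(path, "w", header=header):
        pass
    hc = count_hits_sam(path, major_rg.family, total_reads=1000)
    assert (hc.hits, hc.total_reads) == (0, 1000)


def test_naive_and_sam_paths_agree(tmp_path):
    """Counting via naive_align directly and via a SAM produced from the
    same alignments yields identical HitCounts."""
    rg, _ = simple_rg(seed=9)
    rng = np.random.default_rng(7)
    reads = []
    for i in range(40):
        if rng.random() < 0.6:
            s = int(rng.integers(0, 120 - 36))
            reads.append((f"r{i}", rg.segment_sequence(0)[s:s + 36]))
        else:
            reads.append((f"r{i}", random_seq(rng, 36)))
    direct = count_hits_naive(reads, rg, 2)
    sam = tmp_path / "two.sam"
    write_sam(reads, rg, 2, sam)
    via_sam = count_hits_sam(sam, rg.family)
    assert direct == via_sam


def test_enrichment_fold_and_ci():
    res = enrichment(HitCounts("f", 120, 10_000), HitCounts("f", 100, 10_000))
    assert res.fold == pytest.approx(1.2)
    se = math.sqrt(1 / 120 - 1 / 10_000 + 1 / 100 - 1 / 10_000)
    assert res.ci_low == pytest.approx(1.2 * math.exp(-1.96 * se))
    assert res.ci_high == pytest.approx(1.2 * math.exp(1.96 * se))
    assert res.ci_low <= res.fold <= res.ci_high


def test_enrichment_identity_and_degenerate_cases():
    eq = enrichment(HitCounts("f", 55, 1000), HitCounts("f", 55, 1000))
    assert eq.fold == pytest.approx(1.0)
    undef = enrichment(HitCounts("f", 10, 1000), HitCounts("f", 0, 1000))
    assert undef.undefined and math.isnan(undef.fold)
    zero_chip = enrichment(HitCounts("f", 0, 1000), HitCounts("f", 10, 1000))
    assert zero_chip.fold == 0.0 and not zero_chip.undefined
    with pytest.raises(ValueError, match="family"):
        enrichment(HitCounts("f", 1, 10), HitCounts("g", 1, 10))


def test_raw_ratio_mode():
    res = enrichment(HitCounts("f", 120, 20_000), HitCounts("f", 100, 10_000),
                     normalized=False)
    assert res.fold == pytest.approx(1.2)


@given(st.integers(1, 500), st.integers(1, 500), st.integers(501, 2000),
       st.integers(501, 2000))
def test_enrichment_swap_symmetry(hc, hi, tc, ti):
    """fold(chip, input) = 1 / fold(input, chip)."""
    a = enrichment(HitCounts("f", hc, tc), HitCounts("f", hi, ti))
    b = enrichment(HitCounts("f", hi, ti), HitCounts("f", hc, tc))
    assert a.fold == pytest.approx(1.0 / b.fold)
    assert a.ci_low == pytest.approx(1.0 / b.ci_high)
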
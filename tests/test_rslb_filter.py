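from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

import cdr3pipe as c
from cdr3pipe.motifs import FORWARD_PRIMER, revcomp
from cdr3pipe.rslb_filter import (
    ConfigError,
    LengthWindow,
    QualityGate,
    RSLBConfig,
    dedupe,
    extract_cdr3,
    filter_length,
    filter_quality,
    find_motif,
    has_isotype_motif,
    orient_read,
    run_rslb,
)
from cdr3pipe.seq_io import Read

PRE = "GAGGACACGGCCACATACTACTG"
POST = "TGGGGCCAA"


def _read(seq, phred=20, read_id="r1"):
    return Read(read_id, seq, [phred] * len(seq))


# ---------------------------------------------------------------------------
# length and quality gates


@pytest.mark.parametrize(
    "isotype,length,expected",
    [
        ("IgM", 700, True),
        ("IgM", 699, False),
        ("IgM", 1200, True),
        ("IgM", 1201, False),
        ("IgG", 200, True),
        ("IgG", 800, True),
        ("IgG", 801, False),
    ],
)
def test_filter_length_boundaries(isotype, length, expected):
    window = LengthWindow.for_isotype(isotype)
    assert filter_length(_read("A" * length), window) is expected


def test_filter_quality_all_q20_passes():
    assert filter_quality(_read("A" * 50, phred=20), QualityGate())


def test_filter_quality_all_q10_fails():
    assert not filter_quality(_read("A" * 50, phred=10), QualityGate())


def test_filter_quality_exact_boundary_passes():
    # 40 of 100 bases below threshold: fraction 0.40 is not > 0.40
    read = Read("r", "A" * 100, [10] * 40 + [20] * 60)
    assert filter_quality(read, QualityGate())


def test_invalid_window_rejected():
    with pytest.raises(ConfigError):
        LengthWindow("IgM", 10, 5)


# ---------------------------------------------------------------------------
# motif search


def test_find_motif_exact_primer():
    seq = "T" * 37 + FORWARD_PRIMER + "T" * 25
    assert find_motif(seq, FORWARD_PRIMER, 4) == (37, 0)


def _mutate(seq, positions):
    swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = swap[out[p]]
    return "".join(out)


def test_find_motif_four_mismatches_found():
    mutated = _mutate(FORWARD_PRIMER, [0, 5, 10, 15])
    seq = "T" * 30 + mutated + "T" * 30
    hit = find_motif(seq, FORWARD_PRIMER, 4)
    assert hit == (30, 4)


def test_find_motif_five_mismatches_rejected():
    mutated = _mutate(FORWARD_PRIMER, [0, 5, 10, 15, 19])
    seq = "T" * 30 + mutated + "T" * 30
    assert find_motif(seq, FORWARD_PRIMER, 4) is None


def test_find_motif_leftmost_on_tie():
    seq = "AACCGGTT" * 4
    assert find_motif(seq, "AACC", 0) == (0, 0)


def test_find_motif_longer_than_sequence():
    assert find_motif("ACG", "ACGT", 4) is None


def test_find_motif_n_counts_as_mismatch():
    assert find_motif("ANGT", "ANGT", 0) is None
    assert find_motif("ANGT", "ANGT", 2) == (0, 1)


def _brute_force_best(seq, motif, max_mm):
    if len(motif) > len(seq) or not motif:
        return None
    best = None
    for pos in range(len(seq) - len(motif) + 1):
        window = seq[pos : pos + len(motif)]
        mm = sum(1 for a, b in zip(window, motif) if a != b or a == "N" or b == "N")
        if best is None or mm < best[1]:
            best = (pos, mm)
    return best if best[1] <= max_mm else None


@settings(max_examples=150, deadline=None)
@given(
    seq=st.text(alphabet="ACGTN", min_size=1, max_size=200),
    motif=st.text(alphabet="ACGTN", min_size=1, max_size=25),
    max_mm=st.integers(min_value=0, max_value=6),
)
def test_find_motif_matches_brute_force(seq, motif, max_mm):
    assert find_motif(seq, motif, max_mm) == _brute_force_best(seq, motif, max_mm)


# ---------------------------------------------------------------------------
# orientation


def test_orient_forward_read(primers, clean_igm_sample):
    _, reads, truths = clean_igm_sample
    forward = next(
        r for r, t in zip(reads, truths) if t.orientation == "forward"
    )
    oriented, orientation, outcome = orient_read(forward, primers, "IgM")
    assert (orientation, outcome) == ("as-is", "ok")
    assert oriented.seq == forward.seq


def test_orient_flipped_read_restores_template(primers, clean_igm_sample):
    _, reads, truths = clean_igm_sample
    flipped = next(r for r, t in zip(reads, truths) if t.orientation == "reverse")
    oriented, orientation, outcome = orient_read(flipped, primers, "IgM")
    assert (orientation, outcome) == ("flipped", "ok")
    assert oriented.seq == revcomp(flipped.seq)
    assert oriented.seq.startswith(FORWARD_PRIMER)


def test_orient_no_primer(primers):
    read = _read("ACGT" * 50)
    _, orientation, outcome = orient_read(read, primers, "IgM")
    assert outcome == "no_primer"


def test_orientation_monotone_in_max_mismatch(noisy_igm_sample, motifs):
    _, reads, _ = noisy_igm_sample
    passed_prev = -1
    for max_mm in (0, 2, 4, 6):
        primers = c.PrimerSet(max_mismatch=max_mm)
        passed = sum(
            1 for r in reads if orient_read(r, primers, "IgM")[2] == "ok"
        )
        assert passed >= passed_prev
        passed_prev = passed


# ---------------------------------------------------------------------------
# isotype motif screen


def test_isotype_motif_matches_own_isotype(clean_igm_sample, motifs, primers):
    _, reads, _ = clean_igm_sample
    for read in reads[:30]:
        oriented, _, _ = orient_read(read, primers, "IgM")
        assert has_isotype_motif(oriented.seq, motifs, "IgM")


def test_isotype_motif_rejects_other_isotype(clean_igm_sample, motifs, primers):
    # toy motifs are divergent far beyond their mismatch allowance
    _, reads, _ = clean_igm_sample
    for read in reads[:30]:
        oriented, _, _ = orient_read(read, primers, "IgM")
        assert not has_isotype_motif(oriented.seq, motifs, "IgG")


def test_isotype_motif_empty_list_fails(clean_igm_sample):
    _, reads, _ = clean_igm_sample
    empty = c.MotifLibrary(isotype_motifs={})
    assert not has_isotype_motif(reads[0].seq, empty, "IgM")


# ---------------------------------------------------------------------------
# dedupe


def test_dedupe_keeps_first_occurrence():
    reads = [_read("AA", read_id="a"), _read("CC", read_id="b"), _read("AA", read_id="a")]
    unique, duplicates = dedupe(reads)
    assert [r.id for r in unique] == ["a", "b"]
    assert duplicates == 1


def test_dedupe_all_unique_is_identity():
    reads = [_read("AA", read_id=f"r{i}") for i in range(5)]
    unique, duplicates = dedupe(reads)
    assert unique == reads and duplicates == 0


def test_dedupe_idempotent():
    reads = [_read("AA", read_id=x) for x in ["a", "b", "a", "c", "b"]]
    once, _ = dedupe(reads)
    twice, dups = dedupe(once)
    assert twice == once and dups == 0


# ---------------------------------------------------------------------------
# junction extraction


def test_extract_worked_example(motifs):
    seq = "CACGT" + PRE + "TGCTAAG" + POST + "TTACG"
    result = extract_cdr3(seq, motifs)
    assert result.outcome == "extracted"
    assert result.junction_nt == "TGTGCTAAGTGG"
    assert result.junction_aa == "CAKW"
    assert result.length_aa == 4


def test_extract_frame_error_when_span_shortened(motifs):
    seq = "CACGT" + PRE + "TGCTAA" + POST + "TTACG"
    assert extract_cdr3(seq, motifs).outcome == "frame_error"


def test_extract_anchor_error_when_cysteine_broken(motifs):
    # one mismatch in the pre-motif tail is tolerated by the motif search but
    # corrupts the carried cysteine codon
    pre_broken = PRE[:-1] + "A"
    seq = "CACGT" + pre_broken + "TGCTAAG" + POST + "TTACG"
    result = extract_cdr3(seq, motifs)
    assert result.outcome == "anchor_error"


def test_extract_no_cdr3_without_motifs(motifs):
    assert extract_cdr3("ACGT" * 30, motifs).outcome == "no_cdr3"


def test_extract_simulator_round_trip(motifs, clean_igm_sample, primers):
    _, reads, truths = clean_igm_sample
    for read, truth in zip(reads[:50], truths[:50]):
        oriented, _, _ = orient_read(read, primers, "IgM")
        result = extract_cdr3(oriented.seq, motifs)
        assert result.outcome == "extracted"
        assert result.junction_aa == truth.true_junction_aa
        assert result.length_aa == truth.true_length_aa


# ---------------------------------------------------------------------------
# full cascade


def test_run_rslb_empty_input():
    records, counts = run_rslb([], RSLBConfig(isotype="IgM"))
    assert records == []
    assert counts.total_input == 0
    assert all(v == 0 for v in counts.counts.values())


def test_run_rslb_zero_noise_extracts_everything(clean_igm_sample):
    config, reads, truths = clean_igm_sample
    records, counts = run_rslb(reads, RSLBConfig(isotype="IgM"))
    assert counts.counts["extracted"] == config.n_reads
    truth_by_id = {t.read_id: t for t in truths}
    for record in records:
        assert record.junction_aa == truth_by_id[record.read_id].true_junction_aa


def test_run_rslb_conservation(noisy_igm_sample):
    config, reads, _ = noisy_igm_sample
    _, counts = run_rslb(reads, RSLBConfig(isotype="IgM"))
    assert sum(counts.counts.values()) == counts.total_input == config.n_reads


def test_run_rslb_counts_duplicates(noisy_igm_sample):
    _, reads, truths = noisy_igm_sample
    _, counts = run_rslb(reads, RSLBConfig(isotype="IgM"))
    n_dup_truth = sum(1 for t in truths if t.duplicate_of)
    # errors can knock a duplicate (or its original) out before the dedupe
    # stage, so the outcome count never exceeds the planted count
    assert 0 < counts.counts["duplicate"] <= n_dup_truth


def test_reverse_complement_invariance(clean_igm_sample):
    # stated for reads with intact primer sites: under sequencing errors a
    # damaged forward primer makes recoverability strand-dependent, by
    # construction of the two-branch primer search
    _, reads, _ = clean_igm_sample
    config = RSLBConfig(isotype="IgM")
    records, _ = run_rslb(reads, config)
    rc_reads = [Read(r.id, revcomp(r.seq), r.quals[::-1]) for r in reads]
    rc_records, _ = run_rslb(rc_reads, config)
    extracted = Counter(r.junction_aa for r in records if r.outcome == "extracted")
    rc_extracted = Counter(r.junction_aa for r in rc_records if r.outcome == "extracted")
    assert extracted == rc_extracted


def test_run_rslb_low_quality_reads_fail_gate():
    sim = c.SimConfig(n_reads=40, isotype="IgM", seed=7, lowq_fraction=1.0)
    reads, _ = c.simulate_sample(sim)
    _, counts = run_rslb(reads, RSLBConfig(isotype="IgM"))
    assert counts.counts["fail_quality"] == 40


def test_run_rslb_length_gate_without_padding():
    # unpadded IgM templates are far below the 700 nt minimum
    sim = c.SimConfig(n_reads=20, isotype="IgM", seed=7, pad_to_window=False)
    reads, _ = c.simulate_sample(sim)
    _, counts = run_rslb(reads, RSLBConfig(isotype="IgM"))
    assert counts.counts["fail_length"] == 20


def test_invalid_config_reported_before_processing():
    with pytest.raises(ConfigError):
        run_rslb([_read("A" * 800)], RSLBConfig(isotype="IgX"))
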
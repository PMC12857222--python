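"""Stepwise filtering and junction extraction for heavy-chain amplicons.

The cascade applied to every read, in order:

1. length window (per isotype, inclusive bounds),
2. quality gate (fraction of bases below a Phred threshold),
3. primer-based orientation (forward primer first; otherwise the isotype's
   reverse primer, after which the read is reverse-complemented),
4. isotype-determining motif screen,
5. duplicate removal keyed on the read identifier,
6. anchor-motif junction extraction with frame and C/W anchor checks.

The first failing gate assigns the read's outcome; outcome counters always
sum to the number of input reads.  All motif searches are substitution-only
(Hamming) sliding-window scans; ``N`` counts as a mismatch against anything,
including another ``N``.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .motifs import (
    Motif,
    MotifLibrary,
    PostCdr3Motif,
    PreCdr3Motif,
    PrimerSet,
    default_motif_library,
    default_primer_set,
    revcomp,
)
from .repertoire_metrics import translate_region
from .seq_io import Read

OUTCOMES = (
    "fail_length",
    "fail_quality",
    "no_primer",
    "no_isotype_motif",
    "duplicate",
    "no_cdr3",
    "frame_error",
    "anchor_error",
    "extracted",
)

#: Inclusive per-isotype length windows, in nucleotides.
DEFAULT_WINDOWS = {"IgM": (700, 1200), "IgG": (200, 800)}


class ConfigError(ValueError):
    """Raised for invalid filter configuration, before any read is processed."""


@dataclass(frozen=True)
class LengthWindow:
    isotype: str
    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ConfigError("min_len must be <= max_len")
        if self.min_len < 0:
            raise ConfigError("min_len must be >= 0")

    @classmethod
    def for_isotype(cls, isotype: str) -> "LengthWindow":
        if isotype not in DEFAULT_WINDOWS:
            raise ConfigError(f"no default length window for isotype {isotype!r}")
        lo, hi = DEFAULT_WINDOWS[isotype]
        return cls(isotype, lo, hi)


@dataclass(frozen=True)
class QualityGate:
    """Fail a read when too many bases fall below the qualified Phred score."""

    qualified_phred: int = 15
    max_unqualified_fraction: float = 0.40

    def __post_init__(self) -> None:
        if self.qualified_phred < 0:
            raise ConfigError("qualified_phred must be >= 0")
        if not 0.0 <= self.max_unqualified_fraction <= 1.0:
            raise ConfigError("max_unqualified_fraction must be in [0, 1]")


@dataclass
class ExtractionRecord:
    """Per-read outcome of the filter cascade."""

    read_id: str
    isotype: str
    orientation: str  # "as-is" | "flipped"
    outcome: str
    junction_nt: str = ""
    junction_aa: str = ""
    length_aa: int = 0
    pre_motif_used: str = ""
    post_motif_used: str = ""
    # read coordinates of the junction on the oriented sequence; kept for
    # downstream gene assignment, not serialized in the AIRR-style table
    junction_start: int = -1
    junction_end: int = -1
    oriented_seq: str = ""

    @property
    def length_aa_imgt(self) -> int:
        """Anchor-exclusive junction length (both anchor residues removed)."""
        return max(self.length_aa - 2, 0) if self.outcome == "extracted" else 0


@dataclass
class OutcomeCounts:
    """Conservation audit: one counter per outcome plus the input total."""

    total_input: int = 0
    counts: dict[str, int] = field(default_factory=lambda: {o: 0 for o in OUTCOMES})

    def record(self, outcome: str) -> None:
        self.counts[outcome] += 1
        self.total_input += 1

    def check(self) -> None:
        if sum(self.counts.values()) != self.total_input:
            raise AssertionError("outcome counters do not sum to total input")

    def as_dict(self) -> dict[str, int]:
        out = dict(self.counts)
        out["total_input"] = self.total_input
        return out


# ---------------------------------------------------------------------------
# motif search


_N_BYTE = ord("N")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _mismatch_counts(seq: str, motif: str) -> np.ndarray | None:
    """Hamming mismatch count of ``motif`` at every alignment in ``seq``.

    Returns None when the motif does not fit.  ``N`` mismatches everything,
    including ``N``.
    """
    s = _encode(seq)
    m = _encode(motif)
    if m.size > s.size or m.size == 0:
        return None
    windows = sliding_window_view(s, m.size)
    mm = (windows != m).sum(axis=1)
    # byte equality would let N match N; the contract counts that a mismatch
    if _N_BYTE in m or (s == _N_BYTE).any():
        mm = mm + ((windows == _N_BYTE) & (m == _N_BYTE)).sum(axis=1)
    return mm


def find_motif(seq: str, motif: str, max_mm: int) -> tuple[int, int] | None:
    """Best Hamming hit of ``motif`` in ``seq``: ``(position, mismatches)``.

    Ties are broken leftmost; returns None when every window exceeds
    ``max_mm`` or the motif is longer than the sequence.
    """
    mm = _mismatch_counts(seq, motif)
    if mm is None:
        return None
    pos = int(np.argmin(mm))
    best = int(mm[pos])
    if best > max_mm:
        return None
    return pos, best


def find_motif_hits(seq: str, motif: str, max_mm: int) -> list[tuple[int, int]]:
    """All alignments of ``motif`` in ``seq`` with at most ``max_mm`` mismatches."""
    mm = _mismatch_counts(seq, motif)
    if mm is None:
        return []
    positions = np.flatnonzero(mm <= max_mm)
    return [(int(p), int(mm[p])) for p in positions]


# ---------------------------------------------------------------------------
# individual gates


def filter_length(read: Read, window: LengthWindow) -> bool:
    return window.min_len <= len(read.seq) <= window.max_len


def filter_quality(read: Read, gate: QualityGate) -> bool:
    """Pass unless the unqualified-base fraction exceeds the gate's limit."""
    if not read.quals:
        return True
    bad = sum(1 for q in read.quals if q < gate.qualified_phred)
    return bad / len(read.quals) <= gate.max_unqualified_fraction


def orient_read(
    read: Read, primers: PrimerSet, isotype: str
) -> tuple[Read, str, str]:
    """Return ``(oriented read, orientation, outcome)``.

    The forward-primer branch has priority; a read matching only the
    isotype's reverse primer is reverse-complemented (qualities reversed).
    ``outcome`` is ``"ok"`` or ``"no_primer"``.
    """
    if find_motif(read.seq, primers.forward, primers.max_mismatch) is not None:
        return read, "as-is", "ok"
    reverse = primers.reverse_by_isotype.get(isotype)
    if reverse is not None and find_motif(read.seq, reverse, primers.max_mismatch) is not None:
        flipped = Read(read.id, revcomp(read.seq), read.quals[::-1])
        return flipped, "flipped", "ok"
    return read, "as-is", "no_primer"


def has_isotype_motif(seq: str, motifs: MotifLibrary, isotype: str) -> bool:
    return any(
        find_motif(seq, m.seq, m.allowed_mismatch) is not None
        for m in motifs.motifs_for(isotype)
    )


def dedupe(reads: Sequence[Read]) -> tuple[list[Read], int]:
    """Keep the first occurrence of each read identifier, preserving order."""
    seen: set[str] = set()
    unique: list[Read] = []
    duplicates = 0
    for read in reads:
        if read.id in seen:
            duplicates += 1
        else:
            seen.add(read.id)
            unique.append(read)
    return unique, duplicates


@dataclass
class ExtractionResult:
    outcome: str
    junction_nt: str = ""
    junction_aa: str = ""
    length_aa: int = 0
    pre_motif: str = ""
    post_motif: str = ""
    junction_start: int = -1
    junction_end: int = -1


def extract_cdr3(seq: str, motifs: MotifLibrary) -> ExtractionResult:
    """Locate the pre/post anchor motifs and extract the junction.

    Candidate (pre, post) pairs — post strictly downstream of the pre match —
    are ranked by total mismatches, then leftmost pre-motif position, then
    shortest span.  The junction is the motif-carried cysteine-codon bases,
    the span between the matches, and the motif-carried tryptophan-codon
    bases.  Frame (length divisible by 3) and anchors (first residue C,
    last residue W) are then enforced.
    """
    pre_hits: list[tuple[PreCdr3Motif, int, int]] = []
    for pre in motifs.pre_cdr3:
        for pos, mm in find_motif_hits(seq, pre.seq, pre.allowed_mismatch):
            pre_hits.append((pre, pos, mm))
    post_hits: list[tuple[PostCdr3Motif, int, int]] = []
    for post in motifs.post_cdr3:
        for pos, mm in find_motif_hits(seq, post.seq, post.allowed_mismatch):
            post_hits.append((post, pos, mm))

    best: tuple[int, int, int] | None = None
    chosen: tuple[PreCdr3Motif, int, PostCdr3Motif, int] | None = None
    for pre, ppos, pmm in pre_hits:
        pre_end = ppos + len(pre.seq)
        for post, qpos, qmm in post_hits:
            if qpos < pre_end:
                continue
            key = (pmm + qmm, ppos, qpos - pre_end)
            if best is None or key < best:
                best = key
                chosen = (pre, ppos, post, qpos)
    if chosen is None:
        return ExtractionResult(outcome="no_cdr3")

    pre, ppos, post, qpos = chosen
    pre_end = ppos + len(pre.seq)
    start = pre_end - pre.c104_carry
    end = qpos + post.w118_lead
    junction_nt = seq[start:end]
    if len(junction_nt) % 3 != 0:
        return ExtractionResult(
            outcome="frame_error", pre_motif=pre.seq, post_motif=post.seq
        )
    junction_aa = translate_region(junction_nt)
    if not junction_aa or junction_aa[0] != "C" or junction_aa[-1] != "W":
        return ExtractionResult(
            outcome="anchor_error", pre_motif=pre.seq, post_motif=post.seq
        )
    return ExtractionResult(
        outcome="extracted",
        junction_nt=junction_nt,
        junction_aa=junction_aa,
        length_aa=len(junction_aa),
        pre_motif=pre.seq,
        post_motif=post.seq,
        junction_start=start,
        junction_end=end,
    )


# ---------------------------------------------------------------------------
# full cascade


@dataclass(frozen=True)
class RSLBConfig:
    """Configuration for one sample's run through the cascade."""

    isotype: str = "IgM"
    window: LengthWindow | None = None
    gate: QualityGate = field(default_factory=QualityGate)
    primers: PrimerSet = field(default_factory=default_primer_set)
    motifs: MotifLibrary = field(default_factory=default_motif_library)

    def resolved_window(self) -> LengthWindow:
        return self.window if self.window is not None else LengthWindow.for_isotype(self.isotype)

    def validate(self) -> None:
        self.resolved_window()
        if self.isotype not in self.primers.reverse_by_isotype:
            raise ConfigError(f"no reverse primer configured for isotype {self.isotype!r}")
        if not self.motifs.motifs_for(self.isotype):
            raise ConfigError(f"no isotype motifs configured for {self.isotype!r}")


def run_rslb(
    reads: Iterable[Read],
    config: RSLBConfig,
    keep_oriented_seq: bool = False,
) -> tuple[list[ExtractionRecord], OutcomeCounts]:
    """Apply the full cascade to a stream of reads.

    Returns one :class:`ExtractionRecord` per input read (in order) and the
    conservation audit.  Duplicate detection registers a read identifier
    only once the read has survived all earlier gates, so two copies that
    both fail the length window are both counted as ``fail_length``.
    """
    config.validate()
    window = config.resolved_window()
    counts = OutcomeCounts()
    records: list[ExtractionRecord] = []
    seen_ids: set[str] = set()

    for read in reads:
        record = ExtractionRecord(
            read_id=read.id, isotype=config.isotype, orientation="as-is", outcome=""
        )
        if not filter_length(read, window):
            record.outcome = "fail_length"
        elif not filter_quality(read, config.gate):
            record.outcome = "fail_quality"
        else:
            oriented, orientation, primer_outcome = orient_read(
                read, config.primers, config.isotype
            )
            record.orientation = orientation
            if primer_outcome != "ok":
                record.outcome = "no_primer"
            elif not has_isotype_motif(oriented.seq, config.motifs, config.isotype):
                record.outcome = "no_isotype_motif"
            elif oriented.id in seen_ids:
                record.outcome = "duplicate"
            else:
                seen_ids.add(oriented.id)
                result = extract_cdr3(oriented.seq, config.motifs)
                record.outcome = result.outcome
                record.junction_nt = result.junction_nt
                record.junction_aa = result.junction_aa
                record.length_aa = result.length_aa
                record.pre_motif_used = result.pre_motif
                record.post_motif_used = result.post_motif
                record.junction_start = result.junction_start
                record.junction_end = result.junction_end
                if keep_oriented_seq:
                    record.oriented_seq = oriented.seq
        counts.record(record.outcome)
        records.append(record)

    counts.check()
    return records, counts


#: Column order of the per-sample extraction table (AIRR-inspired).
EXTRACTION_COLUMNS = [
    "sequence_id",
    "isotype",
    "orientation",
    "outcome",
    "junction",
    "junction_aa",
    "junction_length_aa",
    "junction_length_aa_imgt",
]


def extraction_rows(records: Iterable[ExtractionRecord]) -> list[dict[str, object]]:
    """Serialize records for :func:`cdr3pipe.seq_io.write_table`."""
    rows = []
    for r in records:
        extracted = r.outcome == "extracted"
        rows.append(
            {
                "sequence_id": r.read_id,
                "isotype": r.isotype,
                "orientation": r.orientation,
                "outcome": r.outcome,
                "junction": r.junction_nt if extracted else "",
                "junction_aa": r.junction_aa if extracted else "",
                "junction_length_aa": r.length_aa if extracted else "",
                "junction_length_aa_imgt": r.length_aa_imgt if extracted else "",
            }
        )
    return rows
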
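"""Ground-truth amplicon simulator.

Generates FASTQ reads with a known junction, gene origin, orientation,
error count and productivity flag, exercising every branch of the filter
cascade.  Templates are forward-oriented as

    forward primer + V (ends in the pre-CDR3 motif) + junction interior
    + J (starts with the post-CDR3 motif) + isotype motif + pad
    + revcomp(reverse primer)

then optionally mutated, reverse-complemented and duplicated.

Ground-truth cleanliness: the fixed germline parts are built, and each
random junction/pad is rejection-sampled, so that no spurious motif or
primer near-match can divert orientation or junction extraction.  At zero
error rates the filter therefore recovers every planted junction exactly.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterable
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

from .motifs import (
    ISOTYPES,
    MotifLibrary,
    PrimerSet,
    default_motif_library,
    default_primer_set,
    revcomp,
)
from .repertoire_metrics import classify_length, translate_region
from .rslb_filter import DEFAULT_WINDOWS, find_motif, find_motif_hits
from .seq_io import Read, write_fasta, write_table

_NT = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = tuple(
    "".join(c) for c in itertools.product(_NT, repeat=3) if "".join(c) not in _STOPS
)

DEFAULT_LENGTH_RANGES = {
    "short": (5, 10),
    "medium": (11, 39),
    "ultralong": (40, 70),
}


class SimConfigError(ValueError):
    """Raised for invalid simulation configuration."""


class AssemblyError(ValueError):
    """Raised when a junction is inconsistent with the motif bookkeeping."""


# ---------------------------------------------------------------------------
# germline toy database


@dataclass
class GermlineToyDB:
    """Fabricated germline segments with unambiguous simple assignment.

    V genes end with a pre-CDR3 motif; J genes start with a post-CDR3 motif;
    ``constant_motifs`` maps each isotype to the motif placed downstream of
    the J segment.  Same-class genes are built >= 20% divergent and D genes
    share no >= 5 nt substring, so identity/longest-substring assignment is
    exact on error-free reads.
    """

    v_genes: dict[str, str]
    d_genes: dict[str, str]
    j_genes: dict[str, str]
    constant_motifs: dict[str, str]

    def validate(self, motifs: MotifLibrary | None = None) -> None:
        motifs = motifs or default_motif_library()
        pre_seqs = tuple(m.seq for m in motifs.pre_cdr3)
        post_seqs = tuple(m.seq for m in motifs.post_cdr3)
        for pool_name, pool in (
            ("v_genes", self.v_genes),
            ("d_genes", self.d_genes),
            ("j_genes", self.j_genes),
        ):
            if not pool:
                raise SimConfigError(f"{pool_name} must be non-empty")
            for name, seq in pool.items():
                if not seq or set(seq) - set(_NT):
                    raise SimConfigError(f"{pool_name}[{name}] must be uppercase ACGT")
        for name, seq in self.v_genes.items():
            if not any(seq.endswith(p) for p in pre_seqs):
                raise SimConfigError(f"V gene {name} does not end with a pre-CDR3 motif")
        for name, seq in self.j_genes.items():
            if not any(seq.startswith(p) for p in post_seqs):
                raise SimConfigError(f"J gene {name} does not start with a post-CDR3 motif")
        for isotype in self.constant_motifs:
            if isotype not in ISOTYPES:
                raise SimConfigError(f"unknown isotype {isotype!r} in constant_motifs")

    def to_fasta(self, path) -> None:
        merged: dict[str, str] = {}
        merged.update(self.v_genes)
        merged.update(self.d_genes)
        merged.update(self.j_genes)
        write_fasta(merged, path)

    @classmethod
    def from_fasta(cls, path, constant_motifs: dict[str, str] | None = None) -> "GermlineToyDB":
        from .seq_io import read_fasta

        if constant_motifs is None:
            constant_motifs = {
                iso: ms[0].seq for iso, ms in default_motif_library().isotype_motifs.items()
            }
        pools: dict[str, dict[str, str]] = {"V": {}, "D": {}, "J": {}}
        for name, seq in read_fasta(path).items():
            for prefix, pool in (("IGHV", "V"), ("IGHD", "D"), ("IGHJ", "J")):
                if name.startswith(prefix):
                    pools[pool][name] = seq
                    break
            else:
                raise SimConfigError(f"germline record id {name!r} must start with IGHV/IGHD/IGHJ")
        db = cls(
            v_genes=pools["V"],
            d_genes=pools["D"],
            j_genes=pools["J"],
            constant_motifs=constant_motifs,
        )
        db.validate()
        return db


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[i] for i in rng.integers(0, 4, n))


def _clean(seq: str, forbidden: Iterable[tuple[str, int]]) -> bool:
    """True when ``seq`` contains no near-match of any forbidden motif."""
    return all(find_motif(seq, motif, mm) is None for motif, mm in forbidden)


def _divergence(a: str, b: str) -> float:
    """Mismatch fraction of the best sliding alignment of the shorter string."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = max(
        sum(1 for x, y in zip(short, long_[o : o + len(short)]) if x == y)
        for o in range(len(long_) - len(short) + 1)
    )
    return 1.0 - best / len(short)


def _lcs_len(a: str, b: str) -> int:
    best = 0
    for i in range(len(a)):
        for j in range(len(b)):
            k = 0
            while i + k < len(a) and j + k < len(b) and a[i + k] == b[j + k]:
                k += 1
            best = max(best, k)
    return best


def build_toy_db(
    seed: int = 20240, motifs: MotifLibrary | None = None, primers: PrimerSet | None = None
) -> GermlineToyDB:
    """Deterministically fabricate the default toy germline database."""
    motifs = motifs or default_motif_library()
    primers = primers or default_primer_set()
    rng = np.random.default_rng(seed)

    pre = motifs.pre_cdr3[0]
    post = motifs.post_cdr3[0]
    forbidden = [
        (pre.seq, pre.allowed_mismatch),
        (post.seq, post.allowed_mismatch),
        (primers.forward, primers.max_mismatch),
        (revcomp(primers.forward), primers.max_mismatch),
    ]
    for iso_motifs in motifs.isotype_motifs.values():
        for m in iso_motifs:
            forbidden.append((m.seq, m.allowed_mismatch))

    def draw_clean(n: int, extra: Iterable[tuple[str, int]] = ()) -> str:
        for _ in range(1000):
            cand = _random_nt(rng, n)
            if _clean(cand, forbidden) and _clean(cand, extra):
                return cand
        raise SimConfigError("could not draw a clean germline segment")

    def draw_pool(names: list[str], make) -> dict[str, str]:
        for _ in range(200):
            pool = {name: make() for name in names}
            seqs = list(pool.values())
            ok = all(
                _divergence(seqs[i], seqs[j]) >= 0.20
                for i in range(len(seqs))
                for j in range(i + 1, len(seqs))
            )
            if ok:
                return pool
        raise SimConfigError("could not build a divergent germline pool")

    v_genes = draw_pool(
        ["IGHV1-7", "IGHV2-1", "IGHV3-3"], lambda: draw_clean(60) + pre.seq
    )

    def make_d() -> str:
        for _ in range(1000):
            cand = "".join(
                _NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS), 12)
            )
            if _clean(cand, forbidden):
                return cand
        raise SimConfigError("could not draw a clean D gene")

    for _ in range(200):
        d_genes = draw_pool(["IGHD8-2", "IGHD1-1", "IGHD5-3"], make_d)
        seqs = list(d_genes.values())
        if all(
            _lcs_len(seqs[i], seqs[j]) < 5
            for i in range(len(seqs))
            for j in range(i + 1, len(seqs))
        ):
            break
    else:
        raise SimConfigError("could not build substring-disjoint D genes")

    j_genes = draw_pool(
        ["IGHJ2-4", "IGHJ1-6"], lambda: post.seq + draw_clean(30)
    )

    constant_motifs = {
        iso: motifs.isotype_motifs[iso][0].seq for iso in motifs.isotype_motifs
    }
    db = GermlineToyDB(
        v_genes=v_genes, d_genes=d_genes, j_genes=j_genes, constant_motifs=constant_motifs
    )
    db.validate(motifs)
    return db


@lru_cache(maxsize=1)
def default_toy_db() -> GermlineToyDB:
    return build_toy_db()


# ---------------------------------------------------------------------------
# configuration and truth records


@dataclass(frozen=True)
class SimConfig:
    n_reads: int = 1000
    isotype: str = "IgM"
    class_probs: tuple[float, float, float] = (0.2, 0.75, 0.05)  # short, medium, ultralong
    length_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_RANGES)
    )
    stop_rate: float = 0.0
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    flip_rate: float = 0.5
    dup_rate: float = 0.0
    lowq_fraction: float = 0.0
    lowq_phred: int = 8
    base_phred: int = 20
    pad_to_window: bool = True
    seed: int = 0
    read_prefix: str = "read"

    def validate(self) -> None:
        if self.n_reads < 0:
            raise SimConfigError("n_reads must be >= 0")
        if self.isotype not in ISOTYPES:
            raise SimConfigError(f"isotype must be one of {ISOTYPES}")
        probs = self.class_probs
        if len(probs) != 3 or any(p < 0 or p > 1 for p in probs):
            raise SimConfigError("class_probs must be three probabilities")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise SimConfigError("class_probs must sum to 1")
        for rate_name in ("stop_rate", "sub_rate", "ins_rate", "del_rate",
                          "flip_rate", "dup_rate", "lowq_fraction"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise SimConfigError(f"{rate_name} must be in [0, 1]")
        for label in ("short", "medium", "ultralong"):
            if label not in self.length_ranges:
                raise SimConfigError(f"length_ranges missing class {label!r}")
            lo, hi = self.length_ranges[label]
            if lo > hi or lo < 2:
                raise SimConfigError(f"invalid length range for {label!r}")
        if self.length_ranges["short"][1] > 10:
            raise SimConfigError("short range must not exceed 10 aa")
        if self.length_ranges["ultralong"][0] < 40:
            raise SimConfigError("ultralong range must start at >= 40 aa")


@dataclass
class TruthRecord:
    read_id: str
    isotype: str
    true_junction_aa: str
    true_length_aa: int
    true_class: str
    productive_flag: bool
    orientation: str  # "forward" | "reverse"
    n_errors_applied: int
    duplicate_of: str
    v_name: str
    d_name: str
    j_name: str

    def as_row(self) -> dict[str, object]:
        return {
            "read_id": self.read_id,
            "isotype": self.isotype,
            "true_junction_aa": self.true_junction_aa,
            "true_length_aa": self.true_length_aa,
            "true_class": self.true_class,
            "productive_flag": self.productive_flag,
            "orientation": self.orientation,
            "n_errors_applied": self.n_errors_applied,
            "duplicate_of": self.duplicate_of,
            "v_name": self.v_name,
            "d_name": self.d_name,
            "j_name": self.j_name,
        }


TRUTH_COLUMNS = [
    "read_id",
    "isotype",
    "true_junction_aa",
    "true_length_aa",
    "true_class",
    "productive_flag",
    "orientation",
    "n_errors_applied",
    "duplicate_of",
    "v_name",
    "d_name",
    "j_name",
]


def write_truth(truths: Iterable[TruthRecord], path) -> None:
    write_table([t.as_row() for t in truths], path, TRUTH_COLUMNS)


# ---------------------------------------------------------------------------
# junction sampling


@dataclass
class JunctionDraw:
    nt: str
    aa: str
    v_name: str
    d_name: str
    j_name: str


def _junction_is_clean(junction_nt: str, motifs: MotifLibrary) -> bool:
    """No anchor-motif near-hit may precede the true post-motif position.

    Scans the junction beyond the carried cysteine bases, extended by the
    post-motif remainder, and accepts only when the single post hit is the
    terminal tryptophan codon; any pre-motif near-hit inside the junction
    also disqualifies it.
    """
    pre = motifs.pre_cdr3[0]
    post = motifs.post_cdr3[0]
    probe = junction_nt[pre.c104_carry :] + post.seq[post.w118_lead :]
    true_pos = len(junction_nt) - pre.c104_carry - post.w118_lead
    for p in motifs.post_cdr3:
        for pos, _ in find_motif_hits(probe, p.seq, p.allowed_mismatch):
            if pos < true_pos:
                return False
    for p in motifs.pre_cdr3:
        if find_motif_hits(junction_nt, p.seq, p.allowed_mismatch):
            return False
    return True


def sample_junction(
    class_label: str,
    rng: np.random.Generator,
    db: GermlineToyDB,
    length_ranges: dict[str, tuple[int, int]] | None = None,
    motifs: MotifLibrary | None = None,
) -> JunctionDraw:
    """Draw a junction of the requested length class.

    The junction starts with a cysteine codon, ends with the tryptophan
    codon, embeds a contiguous codon-aligned stretch of the chosen D gene,
    and is free of in-frame stops and of spurious anchor-motif near-hits.
    """
    if class_label not in ("short", "medium", "ultralong"):
        raise SimConfigError(f"unknown length class {class_label!r}")
    if not db.v_genes or not db.d_genes or not db.j_genes:
        raise SimConfigError("germline pools must be non-empty")
    length_ranges = length_ranges or DEFAULT_LENGTH_RANGES
    motifs = motifs or default_motif_library()
    lo, hi = length_ranges[class_label]

    v_names = sorted(db.v_genes)
    d_names = sorted(db.d_genes)
    j_names = sorted(db.j_genes)
    v_name = v_names[rng.integers(0, len(v_names))]
    d_name = d_names[rng.integers(0, len(d_names))]
    j_name = j_names[rng.integers(0, len(j_names))]
    d_gene = db.d_genes[d_name]
    d_codons = [d_gene[i : i + 3] for i in range(0, len(d_gene) - len(d_gene) % 3, 3)]

    for _ in range(200):
        length_aa = int(rng.integers(lo, hi + 1))
        n_middle = length_aa - 2
        middle = [
            _NONSTOP_CODONS[i]
            for i in rng.integers(0, len(_NONSTOP_CODONS), n_middle)
        ]
        stretch = min(5, n_middle, len(d_codons))
        if stretch > 0:
            d_start = int(rng.integers(0, len(d_codons) - stretch + 1))
            at = int(rng.integers(0, n_middle - stretch + 1))
            middle[at : at + stretch] = d_codons[d_start : d_start + stretch]
        cys = "TGT" if rng.random() < 0.5 else "TGC"
        junction_nt = cys + "".join(middle) + "TGG"
        if _junction_is_clean(junction_nt, motifs):
            return JunctionDraw(
                nt=junction_nt,
                aa=translate_region(junction_nt),
                v_name=v_name,
                d_name=d_name,
                j_name=j_name,
            )
    raise SimConfigError("could not draw a clean junction")


def plant_stop(junction_nt: str, rng: np.random.Generator) -> str:
    """Replace one interior codon (never an anchor) with a stop codon."""
    n_codons = len(junction_nt) // 3
    if n_codons < 3:
        raise SimConfigError("junction too short to plant an interior stop")
    at = int(rng.integers(1, n_codons - 1))
    stop = _STOPS[rng.integers(0, len(_STOPS))]
    return junction_nt[: 3 * at] + stop + junction_nt[3 * at + 3 :]


# ---------------------------------------------------------------------------
# template assembly


@dataclass
class TemplateLayout:
    template: str
    junction_start: int
    junction_end: int


def build_template(
    junction_nt: str,
    isotype: str,
    db: GermlineToyDB,
    motifs: MotifLibrary | None = None,
    v_name: str | None = None,
    j_name: str | None = None,
    rng: np.random.Generator | None = None,
    pad_to_window: bool = True,
    primers: PrimerSet | None = None,
) -> TemplateLayout:
    """Assemble a forward-oriented template around a junction.

    Raises :class:`AssemblyError` when the junction is inconsistent with the
    motif anchor bookkeeping (frame, cysteine/tryptophan codons, pre-motif
    tail overlap).
    """
    motifs = motifs or default_motif_library()
    primers = primers or default_primer_set()
    pre = motifs.pre_cdr3[0]
    post = motifs.post_cdr3[0]

    if len(junction_nt) % 3 != 0:
        raise AssemblyError("junction length must be divisible by 3")
    if junction_nt[:3] not in ("TGT", "TGC") or not junction_nt.endswith("TGG"):
        raise AssemblyError("junction must start with a Cys codon and end with the Trp codon")
    if pre.c104_carry and junction_nt[: pre.c104_carry] != pre.seq[-pre.c104_carry :]:
        raise AssemblyError("junction start is inconsistent with the pre-motif anchor carry")
    if post.w118_lead and junction_nt[-post.w118_lead :] != post.seq[: post.w118_lead]:
        raise AssemblyError("junction end is inconsistent with the post-motif anchor lead")

    v_name = v_name or sorted(db.v_genes)[0]
    j_name = j_name or sorted(db.j_genes)[0]
    v_seq = db.v_genes[v_name]
    j_seq = db.j_genes[j_name]
    if not v_seq.endswith(pre.seq):
        raise AssemblyError(f"V gene {v_name} does not end with the pre-CDR3 motif")
    if not j_seq.startswith(post.seq):
        raise AssemblyError(f"J gene {j_name} does not start with the post-CDR3 motif")
    isotype_motif = db.constant_motifs[isotype]
    reverse_tail = revcomp(primers.reverse_by_isotype[isotype])

    head = primers.forward + v_seq[: -pre.c104_carry] if pre.c104_carry else primers.forward + v_seq
    core_before_pad = (
        head
        + junction_nt
        + j_seq[post.w118_lead :]
        + isotype_motif
    )
    core_len = len(core_before_pad) + len(reverse_tail)

    pad = ""
    if pad_to_window:
        if rng is None:
            raise AssemblyError("pad_to_window requires an rng")
        lo, hi = DEFAULT_WINDOWS[isotype]
        target = int(rng.integers(max(core_len, lo), hi + 1))
        pad = _random_nt(rng, target - core_len)

    template = core_before_pad + pad + reverse_tail
    junction_start = len(head)
    return TemplateLayout(
        template=template,
        junction_start=junction_start,
        junction_end=junction_start + len(junction_nt),
    )


def _template_ok(
    layout: TemplateLayout,
    isotype: str,
    motifs: MotifLibrary,
    primers: PrimerSet,
) -> bool:
    """Reject templates whose random parts could divert the filter cascade."""
    t = layout.template
    # a reverse-complemented copy must never match the forward primer
    if find_motif(t, revcomp(primers.forward), primers.max_mismatch) is not None:
        return False
    # no cross-isotype motif contamination
    for iso, iso_motifs in motifs.isotype_motifs.items():
        if iso == isotype:
            continue
        for m in iso_motifs:
            if find_motif(t, m.seq, m.allowed_mismatch) is not None:
                return False
    pre = motifs.pre_cdr3[0]
    post = motifs.post_cdr3[0]
    pre_end = layout.junction_start + pre.c104_carry
    true_post = layout.junction_end - post.w118_lead
    # the true pre-motif must be the unique exact hit
    exact_pre = [p for p, mm in find_motif_hits(t, pre.seq, 0)]
    if exact_pre != [pre_end - len(pre.seq)]:
        return False
    # no post-motif near-hit may sit between the pre-motif and the true post
    for p in motifs.post_cdr3:
        for pos, _ in find_motif_hits(t, p.seq, p.allowed_mismatch):
            if pre_end <= pos < true_post:
                return False
    return True


# ---------------------------------------------------------------------------
# error model


def apply_errors(
    seq: str,
    rates: tuple[float, float, float],
    rng: np.random.Generator,
) -> tuple[str, int]:
    """Apply substitutions, insertions and deletions; return (mutated, count).

    Each base is independently deleted or substituted (mutually exclusive);
    each of the ``len(seq) + 1`` inter-base gaps independently receives one
    inserted random base.  The count is the number of edit events.
    """
    sub_rate, ins_rate, del_rate = rates
    for name, r in (("sub", sub_rate), ("ins", ins_rate), ("del", del_rate)):
        if not 0.0 <= r <= 1.0:
            raise SimConfigError(f"{name} rate must be in [0, 1]")
    n = len(seq)
    if n == 0:
        return seq, 0

    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int8)
    for i, base in enumerate(_NT):
        lut[ord(base)] = i
    idx = lut[codes].astype(np.int64)

    u = rng.random(n)
    del_mask = u < del_rate
    sub_mask = (~del_mask) & (u < del_rate + sub_rate)
    ins_mask = rng.random(n + 1) < ins_rate

    shifts = rng.integers(1, 4, n)  # guarantees a different base
    idx[sub_mask] = (idx[sub_mask] + shifts[sub_mask]) % 4

    keep = ~del_mask
    kept = idx[keep]
    ins_positions = np.flatnonzero(ins_mask)
    if ins_positions.size:
        kept_prefix = np.concatenate(([0], np.cumsum(keep)))
        insert_at = kept_prefix[ins_positions]
        ins_bases = rng.integers(0, 4, ins_positions.size)
        kept = np.insert(kept, insert_at, ins_bases)

    out = "".join(_NT[i] for i in kept)
    n_events = int(del_mask.sum() + sub_mask.sum() + ins_positions.size)
    return out, n_events


# ---------------------------------------------------------------------------
# whole-sample simulation


def simulate_sample(
    config: SimConfig,
    db: GermlineToyDB | None = None,
    motifs: MotifLibrary | None = None,
    primers: PrimerSet | None = None,
) -> tuple[list[Read], list[TruthRecord]]:
    """Simulate one sample: FASTQ reads plus a truth record per read.

    Deterministic for a fixed config (including seed).  Duplicates are
    verbatim copies (identifier and sequence) of an earlier read.
    """
    config.validate()
    db = db or default_toy_db()
    motifs = motifs or default_motif_library()
    primers = primers or default_primer_set()
    db.validate(motifs)
    rng = np.random.default_rng(config.seed)
    rates = (config.sub_rate, config.ins_rate, config.del_rate)

    reads: list[Read] = []
    truths: list[TruthRecord] = []
    for i in range(config.n_reads):
        if reads and rng.random() < config.dup_rate:
            j = int(rng.integers(0, len(reads)))
            src = reads[j]
            reads.append(Read(src.id, src.seq, list(src.quals)))
            truths.append(replace(truths[j], duplicate_of=src.id))
            continue

        read_id = f"{config.read_prefix}{i:06d}"
        class_label = ("short", "medium", "ultralong")[
            int(rng.choice(3, p=list(config.class_probs)))
        ]
        for _ in range(200):
            draw = sample_junction(class_label, rng, db, config.length_ranges, motifs)
            junction_nt = draw.nt
            if config.stop_rate > 0 and rng.random() < config.stop_rate:
                planted = plant_stop(junction_nt, rng)
                if not _junction_is_clean(planted, motifs):
                    continue
                junction_nt = planted
            layout = build_template(
                junction_nt,
                config.isotype,
                db,
                motifs,
                v_name=draw.v_name,
                j_name=draw.j_name,
                rng=rng,
                pad_to_window=config.pad_to_window,
                primers=primers,
            )
            if _template_ok(layout, config.isotype, motifs, primers):
                break
        else:
            raise SimConfigError("could not assemble a clean template")

        seq, n_errors = apply_errors(layout.template, rates, rng)
        orientation = "forward"
        if rng.random() < config.flip_rate:
            seq = revcomp(seq)
            orientation = "reverse"
        phred = (
            config.lowq_phred
            if config.lowq_fraction > 0 and rng.random() < config.lowq_fraction
            else config.base_phred
        )
        reads.append(Read(read_id, seq, [phred] * len(seq)))
        junction_aa = translate_region(junction_nt)
        truths.append(
            TruthRecord(
                read_id=read_id,
                isotype=config.isotype,
                true_junction_aa=junction_aa,
                true_length_aa=len(junction_aa),
                true_class=classify_length(len(junction_aa)),
                productive_flag="*" not in junction_aa,
                orientation=orientation,
                n_errors_applied=n_errors,
                duplicate_of="",
                v_name=draw.v_name,
                d_name=draw.d_name,
                j_name=draw.j_name,
            )
        )
    return reads, truths
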
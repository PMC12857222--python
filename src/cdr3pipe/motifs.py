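"""Primer and anchor-motif definitions shared by the simulator and the filter.

The amplicons this toolkit targets carry, in forward orientation:

    forward primer .. V region .. pre-CDR3 motif | junction | post-CDR3
    motif .. J/constant region .. isotype motif .. revcomp(reverse primer)

The pre-CDR3 motif overlaps the first conserved cysteine codon of the
junction (``c104_carry`` nucleotides at its 3' end) and the post-CDR3 motif
overlaps the conserved tryptophan codon (``w118_lead`` nucleotides at its
5' start), so junction extraction stitches motif-carried bases back onto
the span between the two motif matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NT = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Motif:
    """A nucleotide motif searched with a mismatch allowance (Hamming only)."""

    seq: str
    allowed_mismatch: int = 0

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("motif sequence must be non-empty")
        if set(self.seq) - _NT:
            raise ValueError(f"motif {self.seq!r} must be uppercase ACGT")
        if self.allowed_mismatch < 0:
            raise ValueError("allowed_mismatch must be >= 0")


@dataclass(frozen=True)
class PreCdr3Motif(Motif):
    """Motif immediately upstream of the junction.

    The last ``c104_carry`` nucleotides of a match belong to the first
    (cysteine) codon of the junction.
    """

    c104_carry: int = 2

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.c104_carry not in (0, 1, 2):
            raise ValueError("c104_carry must be in {0, 1, 2}")


@dataclass(frozen=True)
class PostCdr3Motif(Motif):
    """Motif immediately downstream of the junction.

    The first ``w118_lead`` nucleotides of a match belong to the last
    (tryptophan) codon of the junction.
    """

    w118_lead: int = 3

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.w118_lead not in (0, 1, 2, 3):
            raise ValueError("w118_lead must be in {0, 1, 2, 3}")


#: Single forward primer used for both isotypes.
FORWARD_PRIMER = "AGATGAACCCACTGTGGACC"

#: Isotype-specific reverse primers (their reverse complement sits at the
#: 3' end of a forward-oriented amplicon).
REVERSE_PRIMERS = {
    "IgM": "TGTTTGGGGCTGAAGTCC",
    "IgG": "GCTGTGGTGGAGGCTGAG",
}

#: Default anchors flanking the junction.
DEFAULT_PRE_CDR3 = PreCdr3Motif("GAGGACACGGCCACATACTACTG", allowed_mismatch=1, c104_carry=2)
DEFAULT_POST_CDR3 = PostCdr3Motif("TGGGGCCAA", allowed_mismatch=1, w118_lead=3)

#: Toy constant-region motifs that identify the isotype downstream of the J
#: segment.  These are fabricated stand-ins, built to be mutually divergent
#: far beyond the mismatch allowance so cross-isotype screening always fails.
DEFAULT_ISOTYPE_MOTIFS = {
    "IgM": (Motif("GGGAGTGCATCCGCCCCAACCCTT", allowed_mismatch=2),),
    "IgG": (Motif("CCACCAAGGGCCCATCGGTCTTCC", allowed_mismatch=2),),
}

ISOTYPES = ("IgM", "IgG")


@dataclass(frozen=True)
class PrimerSet:
    """Forward primer plus per-isotype reverse primers with one mismatch cap."""

    forward: str = FORWARD_PRIMER
    reverse_by_isotype: dict[str, str] = field(default_factory=lambda: dict(REVERSE_PRIMERS))
    max_mismatch: int = 4

    def __post_init__(self) -> None:
        if not self.forward or set(self.forward) - _NT:
            raise ValueError("forward primer must be non-empty uppercase ACGT")
        for iso, p in self.reverse_by_isotype.items():
            if not p or set(p) - _NT:
                raise ValueError(f"reverse primer for {iso} must be non-empty uppercase ACGT")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")


@dataclass(frozen=True)
class MotifLibrary:
    """Isotype-determining motifs plus pre-/post-junction anchor motifs."""

    isotype_motifs: dict[str, tuple[Motif, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ISOTYPE_MOTIFS)
    )
    pre_cdr3: tuple[PreCdr3Motif, ...] = (DEFAULT_PRE_CDR3,)
    post_cdr3: tuple[PostCdr3Motif, ...] = (DEFAULT_POST_CDR3,)

    def __post_init__(self) -> None:
        if not self.pre_cdr3 or not self.post_cdr3:
            raise ValueError("pre_cdr3 and post_cdr3 motif lists must be non-empty")

    def motifs_for(self, isotype: str) -> tuple[Motif, ...]:
        return tuple(self.isotype_motifs.get(isotype, ()))


def default_primer_set() -> PrimerSet:
    return PrimerSet()


def default_motif_library() -> MotifLibrary:
    return MotifLibrary()
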
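"""Junction classification, productivity, gene assignment and clonotypes.

Percentages are reported against two denominators: every sequence with an
extracted junction ("total"), and the stop-codon-free subset ("productive").
Undefined percentages (zero denominator) are ``None`` and serialize as
``NA`` so absence of data is distinguishable from a true 0%.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    _CODON_TO_AA[_stop] = "*"


def translate_region(nt: str) -> str:
    """Translate with the standard code; stops are ``*``; codons containing
    ``N`` (or any non-ACGT character) become ``X``."""
    if len(nt) % 3 != 0:
        raise ValueError(f"length {len(nt)} is not divisible by 3")
    return "".join(
        _CODON_TO_AA.get(nt[i : i + 3], "X") for i in range(0, len(nt), 3)
    )


def is_productive(aa: str) -> bool:
    """A junction is productive when its translation carries no stop codon."""
    return "*" not in aa


@dataclass(frozen=True)
class ClassThresholds:
    """Junction length classes in amino acids (anchor-inclusive)."""

    short_max: int = 10
    ultralong_min: int = 40

    def __post_init__(self) -> None:
        if self.short_max >= self.ultralong_min:
            raise ValueError("short_max must be < ultralong_min")


DEFAULT_THRESHOLDS = ClassThresholds()

CLASS_LABELS = ("short", "medium", "ultralong")


def classify_length(length_aa: int, thresholds: ClassThresholds = DEFAULT_THRESHOLDS) -> str:
    if length_aa < 1:
        raise ValueError("length_aa must be >= 1")
    if length_aa <= thresholds.short_max:
        return "short"
    if length_aa >= thresholds.ultralong_min:
        return "ultralong"
    return "medium"


# ---------------------------------------------------------------------------
# per-sample summary


@dataclass
class RepertoireSummary:
    sample_id: str
    isotype: str
    n_cdr3_total: int
    n_productive: int
    n_ultralong_total: int
    n_ultralong_productive: int
    pct_ultralong_total: float | None
    pct_ultralong_productive: float | None
    pct_short: float | None
    pct_medium: float | None
    pct_ultralong: float | None
    gene_usage: dict[str, dict[str, float]] = field(default_factory=dict)

    def as_row(self) -> dict[str, object]:
        def fmt(v: float | None) -> object:
            return "NA" if v is None else v

        return {
            "sample_id": self.sample_id,
            "isotype": self.isotype,
            "n_cdr3_total": self.n_cdr3_total,
            "n_productive": self.n_productive,
            "n_ultralong_total": self.n_ultralong_total,
            "n_ultralong_productive": self.n_ultralong_productive,
            "pct_ultralong_total": fmt(self.pct_ultralong_total),
            "pct_ultralong_productive": fmt(self.pct_ultralong_productive),
            "pct_short": fmt(self.pct_short),
            "pct_medium": fmt(self.pct_medium),
            "pct_ultralong": fmt(self.pct_ultralong),
        }


SUMMARY_COLUMNS = [
    "sample_id",
    "isotype",
    "n_cdr3_total",
    "n_productive",
    "n_ultralong_total",
    "n_ultralong_productive",
    "pct_ultralong_total",
    "pct_ultralong_productive",
    "pct_short",
    "pct_medium",
    "pct_ultralong",
]


def summarize_sample(
    records: Iterable,
    thresholds: ClassThresholds = DEFAULT_THRESHOLDS,
    sample_id: str = "",
    isotype: str = "",
) -> RepertoireSummary:
    """Count and classify the extracted junctions of one sample.

    ``records`` are extraction records (any objects exposing ``outcome``,
    ``junction_aa`` and ``length_aa``); only ``outcome == "extracted"``
    entries contribute.  Class percentages use the productive denominator.
    """
    n_total = 0
    n_productive = 0
    n_ultra_total = 0
    n_ultra_productive = 0
    class_counts = Counter()
    for r in records:
        if r.outcome != "extracted":
            continue
        n_total += 1
        label = classify_length(r.length_aa, thresholds)
        if label == "ultralong":
            n_ultra_total += 1
        if is_productive(r.junction_aa):
            n_productive += 1
            class_counts[label] += 1
            if label == "ultralong":
                n_ultra_productive += 1

    def pct(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    return RepertoireSummary(
        sample_id=sample_id,
        isotype=isotype,
        n_cdr3_total=n_total,
        n_productive=n_productive,
        n_ultralong_total=n_ultra_total,
        n_ultralong_productive=n_ultra_productive,
        pct_ultralong_total=pct(n_ultra_total, n_total),
        pct_ultralong_productive=pct(n_ultra_productive, n_productive),
        pct_short=pct(class_counts["short"], n_productive),
        pct_medium=pct(class_counts["medium"], n_productive),
        pct_ultralong=pct(class_counts["ultralong"], n_productive),
    )


# ---------------------------------------------------------------------------
# simplified germline gene assignment


@dataclass(frozen=True)
class GeneCall:
    v_name: str | None
    d_name: str | None
    j_name: str | None
    v_identity: float = 0.0
    j_identity: float = 0.0
    d_match_len: int = 0


@dataclass(frozen=True)
class AssignParams:
    min_overlap: int = 30
    min_identity: float = 0.7
    min_d_len: int = 5


def _best_identity(region: str, gene: str, min_overlap: int) -> float:
    """Best end-gap-free overlap identity of ``gene`` against ``region``.

    All ungapped alignments (including overhangs at either end) with at
    least ``min_overlap`` aligned bases are scanned; identity is matches
    over the overlap length.
    """
    n, m = len(region), len(gene)
    if n < min_overlap or m < min_overlap:
        return 0.0
    best = 0.0
    for shift in range(-(m - min_overlap), n - min_overlap + 1):
        start = max(0, -shift)
        end = min(m, n - shift)
        overlap = end - start
        if overlap < min_overlap:
            continue
        matches = sum(1 for j in range(start, end) if gene[j] == region[shift + j])
        best = max(best, matches / overlap)
    return best


def _longest_common_substring(a: str, b: str) -> int:
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    best = 0
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def assign_genes(
    record,
    oriented_seq: str,
    db,
    params: AssignParams = AssignParams(),
) -> GeneCall:
    """Best-identity V/J and longest-exact-substring D call for one record.

    ``db`` is a germline database exposing ``v_genes``/``d_genes``/``j_genes``
    name-to-sequence maps.  Ties are broken by lexicographic gene name;
    below-threshold segments are unassigned (None).
    """
    if record.outcome != "extracted":
        raise ValueError("gene assignment requires an extracted record")
    upstream = oriented_seq[: record.junction_start]
    downstream = oriented_seq[record.junction_end :]

    def best_segment(region: str, genes: Mapping[str, str]) -> tuple[str | None, float]:
        name, identity = None, 0.0
        for gene_name in sorted(genes):
            ident = _best_identity(region, genes[gene_name], params.min_overlap)
            if ident > identity:
                name, identity = gene_name, ident
        if identity < params.min_identity:
            return None, identity
        return name, identity

    v_name, v_identity = best_segment(upstream, db.v_genes)
    j_name, j_identity = best_segment(downstream, db.j_genes)

    interior = record.junction_nt[3:-3]
    d_name, d_len = None, 0
    for gene_name in sorted(db.d_genes):
        match = _longest_common_substring(interior, db.d_genes[gene_name])
        if match > d_len:
            d_name, d_len = gene_name, match
    if d_len < params.min_d_len:
        d_name, d_len = None, 0

    return GeneCall(
        v_name=v_name,
        d_name=d_name,
        j_name=j_name,
        v_identity=v_identity,
        j_identity=j_identity,
        d_match_len=d_len,
    )


def read_gene_calls(path) -> dict[str, GeneCall]:
    """Import an external gene-call TSV (sequence_id, v_call, d_call, j_call).

    Allele suffixes (e.g. ``*01``) are preserved verbatim.  Empty fields map
    to None.
    """
    from .seq_io import read_table

    calls: dict[str, GeneCall] = {}
    for row in read_table(path):
        calls[row["sequence_id"]] = GeneCall(
            v_name=row.get("v_call") or None,
            d_name=row.get("d_call") or None,
            j_name=row.get("j_call") or None,
        )
    return calls


# ---------------------------------------------------------------------------
# clonotypes and gene usage


@dataclass(frozen=True)
class ClonotypeKey:
    v_name: str
    d_name: str
    j_name: str
    junction_aa: str


def _valid_clonotype_junction(aa: str) -> bool:
    return (
        len(aa) >= 2
        and "*" not in aa
        and aa[0] == "C"
        and aa[-1] in ("W", "F")
    )


def collapse_clonotypes(
    records: Iterable,
    gene_calls: Mapping[str, GeneCall],
) -> Counter:
    """Collapse extracted records into clonotypes keyed by (V, D, J, junction).

    Records must be extracted, have an in-frame stop-free junction with C/W-F
    anchors, and carry V and J calls; an unassigned D is recorded as an empty
    string (short junctions often leave no identifiable D remnant).
    """
    table: Counter = Counter()
    for r in records:
        if r.outcome != "extracted" or not _valid_clonotype_junction(r.junction_aa):
            continue
        call = gene_calls.get(r.read_id)
        if call is None or call.v_name is None or call.j_name is None:
            continue
        key = ClonotypeKey(
            v_name=call.v_name,
            d_name=call.d_name or "",
            j_name=call.j_name,
            junction_aa=r.junction_aa,
        )
        table[key] += 1
    return table


def gene_usage(
    records: Iterable,
    gene_calls: Mapping[str, GeneCall],
    basis: str = "reads",
) -> dict[str, dict[str, float]]:
    """Percent usage per gene, on a read or clonotype basis.

    Returns ``{"V": {gene: pct}, "D": ..., "J": ...}``.  Unassigned segments
    are excluded from the numerators but kept in the denominator, so each
    segment class sums to at most 100%.
    """
    if basis not in ("reads", "clonotypes"):
        raise ValueError("basis must be 'reads' or 'clonotypes'")

    counters = {"V": Counter(), "D": Counter(), "J": Counter()}
    if basis == "reads":
        total = 0
        for r in records:
            if r.outcome != "extracted":
                continue
            call = gene_calls.get(r.read_id)
            if call is None:
                continue
            total += 1
            for seg, name in (("V", call.v_name), ("D", call.d_name), ("J", call.j_name)):
                if name:
                    counters[seg][name] += 1
    else:
        clonotypes = collapse_clonotypes(records, gene_calls)
        total = len(clonotypes)
        for key in clonotypes:
            counters["V"][key.v_name] += 1
            if key.d_name:
                counters["D"][key.d_name] += 1
            counters["J"][key.j_name] += 1

    if total == 0:
        return {seg: {} for seg in counters}
    return {
        seg: {name: 100.0 * n / total for name, n in sorted(counter.items())}
        for seg, counter in counters.items()
    }
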
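"""Build IS loci from raw search hits and annotate their structure.

A locus is one genomic copy of an IS, assembled by chaining nearby hits
of the same IS type and strand.  Completeness (complete vs partial
"scar") is decided from how much of the consensus the locus covers and
whether its genomic length falls within the catalog size range.
Structural evidence is then attached: the target-site duplication (the
short direct repeat of host sequence flanking a fresh insertion) and
the terminal inverted repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .align import hamming, revcomp
from .catalog import ISRecord, Replicon
from .search import Hit

DEFAULT_MERGE_GAP = 100
DEFAULT_COMPLETE_COV = 0.95
DEFAULT_IR_PROBE = 25
DEFAULT_IR_MAX_MISMATCH = 3


@dataclass(frozen=True)
class ISLocus:
    """One detected genomic IS copy (0-based half-open coordinates)."""

    is_name: str
    replicon_id: str
    start: int
    end: int
    strand: str
    status: str = "partial"
    coverage: float = 0.0
    tsd_seq: str | None = None
    ir_evidence: str = "none"
    supporting_hits: tuple[Hit, ...] = field(default=(), compare=False)
    edge_flag: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple:
        return (self.replicon_id, self.is_name, self.start, self.end)


def _union_length(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_lo, cur_hi = intervals[0]
    for lo, hi in intervals[1:]:
        if lo > cur_hi:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    total += cur_hi - cur_lo
    return total


def _consensus_interval(hit: Hit, rec: ISRecord) -> tuple[int, int] | None:
    """Project a hit's aligned query interval onto consensus nucleotides.

    Nucleotide hits carry consensus coordinates directly.  Translated
    hits are in amino acids of a reference protein; they are projected
    through the located CDS of that protein in the consensus, or
    dropped from the coverage union when the CDS is unknown.
    """
    if hit.level == "nucleotide":
        return (hit.q_start, hit.q_end)
    if not rec.cds_intervals:
        return None
    refs = [p.name for p in rec.transposase_refs]
    try:
        idx = refs.index(hit.ref_name) if hit.ref_name in refs else 0
        cds = rec.cds_intervals[idx]
    except IndexError:
        return None
    cds_start, cds_end, cds_strand = cds
    aa_lo, aa_hi = hit.q_start, hit.q_end
    if cds_strand == "+":
        return (cds_start + 3 * aa_lo, min(cds_start + 3 * aa_hi, cds_end))
    return (max(cds_end - 3 * aa_hi, cds_start), cds_end - 3 * aa_lo)


def merge_hits(
    hits: list[Hit],
    rec_by_name: dict[str, ISRecord],
    max_gap: int = DEFAULT_MERGE_GAP,
) -> list[ISLocus]:
    """Chain hits of one replicon into loci.

    Hits of the same IS type and strand whose genomic gap is at most
    ``max_gap`` merge into one locus; nucleotide- and translated-level
    hits co-support a locus.  Locus coverage is the union of
    consensus intervals covered, as a fraction of consensus length.
    """
    if not hits:
        return []
    replicon_ids = {h.replicon_id for h in hits}
    if len(replicon_ids) != 1:
        raise ValueError("merge_hits expects hits from a single replicon")
    loci: list[ISLocus] = []
    by_group: dict[tuple[str, str], list[Hit]] = {}
    for h in hits:
        by_group.setdefault((h.is_name, h.strand), []).append(h)
    for (is_name, strand), group in sorted(by_group.items()):
        rec = rec_by_name[is_name]
        group.sort(key=lambda h: (h.start, h.end))
        chain: list[Hit] = [group[0]]
        chains: list[list[Hit]] = [chain]
        for h in group[1:]:
            if h.start - max(x.end for x in chain) <= max_gap:
                chain.append(h)
            else:
                chain = [h]
                chains.append(chain)
        for ch in chains:
            intervals = [iv for h in ch if (iv := _consensus_interval(h, rec)) is not None]
            coverage = min(1.0, _union_length(intervals) / rec.length)
            loci.append(
                ISLocus(
                    is_name=is_name,
                    replicon_id=ch[0].replicon_id,
                    start=min(h.start for h in ch),
                    end=max(h.end for h in ch),
                    strand=strand,
                    coverage=coverage,
                    supporting_hits=tuple(ch),
                )
            )
    loci.sort(key=lambda l: (l.start, l.end, l.is_name))
    return loci


def classify_completeness(
    locus: ISLocus, rec: ISRecord, complete_cov_min: float = DEFAULT_COMPLETE_COV
) -> str:
    """Complete iff coverage >= threshold and length inside the size window.

    The size window is [0.9 * min, 1.1 * max] of the catalog length
    range (unbounded when the catalog gives no range); the coverage
    boundary is inclusive.
    """
    if locus.coverage >= complete_cov_min:
        if rec.length_range is None:
            return "complete"
        lo, hi = rec.length_range
        if 0.9 * lo <= locus.length <= 1.1 * hi:
            return "complete"
    return "partial"


def detect_tsd(replicon: Replicon, locus: ISLocus, rec: ISRecord) -> tuple[str | None, bool]:
    """Target-site duplication at a locus.

    Returns (tsd_seq, edge_flag).  The duplication is called iff the
    ``dr_len``-bp windows immediately flanking the locus are identical;
    loci too close to a replicon edge return (None, True).
    """
    t = rec.dr_len
    if t == 0:
        return None, False
    if locus.start - t < 0 or locus.end + t > replicon.length_bp:
        return None, True
    left = replicon.seq[locus.start - t : locus.start]
    right = replicon.seq[locus.end : locus.end + t]
    if left == right and "N" not in left:
        return left, False
    return None, False


def detect_ir(
    replicon: Replicon,
    locus: ISLocus,
    rec: ISRecord,
    max_mismatch: int = DEFAULT_IR_MAX_MISMATCH,
    probe_len: int = DEFAULT_IR_PROBE,
) -> str:
    """Evidence for terminal inverted repeats at a locus.

    The locus sequence is oriented to the IS frame (reverse-complemented
    for minus-strand copies) and its termini are compared with the
    catalog IRs, or with the consensus termini when the catalog gives
    none.  Returns one of ``both``, ``left``, ``right``, ``none``.
    """
    seq = replicon.seq[locus.start : locus.end]
    if locus.strand == "-":
        seq = revcomp(seq)
    left_probe = rec.ir_left or rec.consensus_seq[:probe_len]
    right_probe = rec.ir_right or rec.consensus_seq[-probe_len:]
    left_ok = len(seq) >= len(left_probe) and hamming(
        seq[: len(left_probe)], left_probe
    ) <= max_mismatch
    right_ok = len(seq) >= len(right_probe) and hamming(
        seq[-len(right_probe) :], right_probe
    ) <= max_mismatch
    if left_ok and right_ok:
        return "both"
    if left_ok:
        return "left"
    if right_ok:
        return "right"
    return "none"


def build_loci(
    replicon: Replicon,
    hits: list[Hit],
    records: list[ISRecord],
    max_gap: int = DEFAULT_MERGE_GAP,
    complete_cov_min: float = DEFAULT_COMPLETE_COV,
) -> list[ISLocus]:
    """Full locus construction for one replicon: merge, classify, annotate."""
    rec_by_name = {r.name: r for r in records}
    out = []
    for locus in merge_hits(hits, rec_by_name, max_gap=max_gap):
        rec = rec_by_name[locus.is_name]
        status = classify_completeness(locus, rec, complete_cov_min)
        tsd, edge = detect_tsd(replicon, locus, rec)
        ir = detect_ir(replicon, locus, rec)
        out.append(replace(locus, status=status, tsd_seq=tsd, ir_evidence=ir, edge_flag=edge))
    return out
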
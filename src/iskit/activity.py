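"""Transposase-integrity assessment of complete IS loci.

A complete IS copy is "putatively active" when its transposase coding
capacity is intact: either a single ORF whose product aligns over at
least 90% of a reference transposase, or - for IS types known to carry
the transposase as two consecutive reading frames (the ISTth7
situation) - a pair of same-strand ORFs matching the N- and C-terminal
halves of the reference in genomic order.  Catalytic-motif content
(DDE / DEDD acidic triads) is reported as an annotation only and never
changes a verdict, since motif class groups IS types rather than
distinguishing live copies from dead ones.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import encode_protein, local_align_all, revcomp
from .catalog import ISRecord
from .loci import ISLocus
from .search import SearchConfig

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

DEFAULT_MIN_AA = 80
DEFAULT_REF_COV_MIN = 0.90
DEFAULT_SPLIT_OVERLAP_MAX = 30
DEFAULT_MOTIF_GAP = (40, 160)

_CODON_TABLE_11 = None


def _translate(seq: str) -> str:
    from Bio.Seq import Seq

    trimmed = seq[: 3 * (len(seq) // 3)]
    return str(Seq(trimmed).translate(table=11))


@dataclass(frozen=True)
class ORFCall:
    """One open reading frame, in local coordinates of the scanned sequence.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on
    the forward strand of the scanned sequence; the ORF includes its
    stop codon, so ``aa_len == (end - start) / 3 - 1``.
    """

    start: int
    end: int
    frame: int
    strand: str
    aa_len: int
    protein: str
    premature_stop: bool = False

    def __post_init__(self) -> None:
        if self.aa_len != (self.end - self.start) // 3 - 1:
            raise ValueError("aa_len inconsistent with coordinates")


@dataclass(frozen=True)
class ActivityCall:
    """Verdict for one complete locus."""

    locus_key: tuple
    verdict: str  # active | inactive
    reason: str   # full_orf | split_orf_pair | truncated | frameshift | interrupted
    motif_found: bool | None = None
    motif_positions: tuple[int, ...] = ()
    notes: tuple[str, ...] = ()


def find_orfs(seq: str, min_aa: int = DEFAULT_MIN_AA) -> list[ORFCall]:
    """All ORFs of >= min_aa residues on both strands (translation table 11).

    Per frame, each stop-to-stop segment contributes at most one ORF,
    opened at its first start codon (ATG/GTG/TTG) and closed at the
    stop; segments without an in-sequence stop codon are skipped.
    Coordinates are on the forward strand of ``seq``.
    """
    n = len(seq)
    out: list[ORFCall] = []
    for strand in ("+", "-"):
        s = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            start_candidate: int | None = None
            for pos in range(frame, n - 2, 3):
                codon = s[pos : pos + 3]
                if codon in STOP_CODONS:
                    if start_candidate is not None:
                        orf_start, orf_end = start_candidate, pos + 3
                        aa_len = (orf_end - orf_start) // 3 - 1
                        if aa_len >= min_aa:
                            if strand == "+":
                                g_start, g_end = orf_start, orf_end
                            else:
                                g_start, g_end = n - orf_end, n - orf_start
                            out.append(
                                ORFCall(
                                    start=g_start,
                                    end=g_end,
                                    frame=frame,
                                    strand=strand,
                                    aa_len=aa_len,
                                    protein=_translate(s[orf_start : orf_end - 3]),
                                )
                            )
                    start_candidate = None
                elif start_candidate is None and codon in START_CODONS:
                    start_candidate = pos
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


def _ref_alignment(orf: ORFCall, ref_seq: str, cfg: SearchConfig):
    """Best local alignment of an ORF product against a reference protein.

    Returns (ref_start, ref_end, identity) of the best-scoring alignment
    at identity >= aa_identity_min, or None.
    """
    alns = local_align_all(
        encode_protein(ref_seq),
        encode_protein(orf.protein),
        cfg.aa_scoring,
        min_score=max(1, cfg.min_dp_score("translated") // 2),
        max_alignments=5,
    )
    best = None
    for a in alns:
        if a.identity < cfg.aa_identity_min:
            continue
        if best is None or a.score > best.score:
            best = a
    if best is None:
        return None
    return best.q_start, best.q_end, best.identity


def assess_activity(
    locus: ISLocus,
    rec: ISRecord,
    orfs: list[ORFCall],
    cfg: SearchConfig | None = None,
    ref_cov_min: float = DEFAULT_REF_COV_MIN,
    split_overlap_max: int = DEFAULT_SPLIT_OVERLAP_MAX,
) -> ActivityCall:
    """Decide whether a complete locus encodes an intact transposase.

    ``orfs`` are ORFs of the locus sequence *oriented to the IS frame*
    (i.e. found on the reverse complement for minus-strand loci, which
    :func:`assess_locus` handles).  Reference coverage is measured on
    the reference protein, so insertions in the copy do not inflate it.
    """
    cfg = cfg or SearchConfig()
    if locus.status != "complete":
        raise ValueError("activity is only assessed for complete loci")
    if not rec.transposase_refs:
        raise ValueError(f"{rec.name}: no transposase reference proteins")
    if not orfs:
        return ActivityCall(locus.key, "inactive", "truncated")

    plus_orfs = sorted((o for o in orfs if o.strand == "+"), key=lambda o: o.start)
    per_ref_status: list[tuple[str, str]] = []  # (verdict, reason) per reference
    for ref in rec.transposase_refs:
        ref_len = len(ref.seq)
        spans = []  # (orf, ref_start, ref_end)
        for orf in plus_orfs:
            aln = _ref_alignment(orf, ref.seq, cfg)
            if aln is not None:
                spans.append((orf, aln[0], aln[1]))
        if not spans:
            per_ref_status.append(("inactive", "truncated"))
            continue
        # (a) one ORF covering >= ref_cov_min of the reference
        best_single = max(spans, key=lambda t: t[2] - t[1])
        if (best_single[2] - best_single[1]) / ref_len >= ref_cov_min:
            per_ref_status.append(("active", "full_orf"))
            continue
        # (b) split-ORF pair for tolerant types: N-half then C-half in order
        if rec.split_orf_tolerant and len(spans) >= 2:
            found_pair = False
            for (o1, r1a, r1b), (o2, r2a, r2b) in zip(spans, spans[1:]):
                joint = (r1b - r1a) + (r2b - r2a) - max(0, r1b - r2a)
                if (
                    o1.frame == o2.frame  # stop-and-restart; frame change = frameshift
                    and o1.start < o2.start
                    and r1a <= r2a
                    and r1a < ref_len / 2
                    and r2b > ref_len / 2
                    and max(0, r1b - r2a) <= split_overlap_max
                    and joint / ref_len >= ref_cov_min
                ):
                    found_pair = True
                    break
            if found_pair:
                per_ref_status.append(("active", "split_orf_pair"))
                continue
        # failure diagnosis
        frames = {(o.frame, o.strand) for o, _, _ in spans}
        union = 0
        last = 0
        for _, ra, rb in sorted(spans, key=lambda t: t[1]):
            union += max(0, rb - max(ra, last))
            last = max(last, rb)
        if union / ref_len >= ref_cov_min and len(frames) > 1:
            per_ref_status.append(("inactive", "frameshift"))
        elif union / ref_len >= ref_cov_min:
            per_ref_status.append(("inactive", "interrupted"))
        else:
            per_ref_status.append(("inactive", "truncated"))

    # every reference transposase must be intact for the copy to be active
    if all(v == "active" for v, _ in per_ref_status):
        reason = (
            "split_orf_pair"
            if any(r == "split_orf_pair" for _, r in per_ref_status)
            else "full_orf"
        )
        verdict = "active"
    else:
        verdict = "inactive"
        reason = next(r for v, r in per_ref_status if v == "inactive")

    motif_found: bool | None = None
    positions: tuple[int, ...] = ()
    notes: tuple[str, ...] = ()
    if rec.motif_class in ("DDE", "DEDD") and plus_orfs:
        longest = max(plus_orfs, key=lambda o: o.aa_len)
        motif_found, pos = motif_check(longest.protein, rec.motif_class)
        positions = tuple(pos)
        if not motif_found:
            notes = ("motif_absent_note",)
    return ActivityCall(locus.key, verdict, reason, motif_found, positions, notes)


def motif_check(
    protein: str,
    motif_class: str,
    gap_window: tuple[int, int] = DEFAULT_MOTIF_GAP,
) -> tuple[bool, list[int]]:
    """Search for the ordered catalytic acidic-residue pattern.

    DDE is D..D..E and DEDD is D..E..D..D, with each inter-residue gap
    inside ``gap_window`` (residues).  Returns the lexicographically
    first matching position tuple.  Advisory: callers must not use this
    to flip activity verdicts.
    """
    if motif_class == "DDE":
        pattern = "DDE"
    elif motif_class == "DEDD":
        pattern = "DEDD"
    else:
        raise ValueError(f"unknown motif class {motif_class!r}")
    lo, hi = gap_window
    pools = [[i for i, aa in enumerate(protein) if aa == res] for res in pattern]

    def extend(prefix: list[int], depth: int) -> list[int] | None:
        if depth == len(pattern):
            return prefix
        for p in pools[depth]:
            if prefix and not (lo <= p - prefix[-1] <= hi):
                if p - prefix[-1] > hi:
                    break
                continue
            result = extend(prefix + [p], depth + 1)
            if result is not None:
                return result
        return None

    hit = extend([], 0)
    return (hit is not None), (hit or [])


def assess_locus(
    replicon_seq: str,
    locus: ISLocus,
    rec: ISRecord,
    cfg: SearchConfig | None = None,
    min_aa: int = DEFAULT_MIN_AA,
) -> ActivityCall:
    """Convenience wrapper: extract, orient, scan ORFs and assess one locus."""
    seq = replicon_seq[locus.start : locus.end]
    if locus.strand == "-":
        seq = revcomp(seq)
    orfs = find_orfs(seq, min_aa=min_aa)
    return assess_activity(locus, rec, orfs, cfg=cfg)
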
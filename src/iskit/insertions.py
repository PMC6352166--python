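"""Call novel IS insertion sites from soft-clipped read alignments.

When a strain carries an IS copy absent from the reference it was
mapped against, reads spanning either junction align only partially:
the overhang into the element is soft-clipped.  Clips therefore pile
up at the two junction coordinates, and their sequence matches one
terminus of the inserted element.  The caller extracts qualifying
clipped read ends, clusters them per reference position and side,
matches each cluster's consensus against the termini of catalog IS
consensus sequences, and pairs a right-side cluster with a nearby
left-side cluster into one insertion call.  Because insertion
duplicates the target site, the right-side clip boundary sits
``tsd_len - 1`` bases to the right of the left-side one; the offset
between the paired flanks recovers the duplication length.

Cross-sample comparison merges reference IS loci with the calls of any
number of derived samples into a presence/absence matrix of candidate
sites, from which per-sample novel counts and pairwise shared-novel
counts are read off.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
import pysam

from .align import revcomp
from .catalog import ISRecord
from .loci import ISLocus

DEFAULT_MIN_CLIP_LEN = 10
DEFAULT_MIN_MAPQ = 20
DEFAULT_CLUSTER_WINDOW = 10
DEFAULT_MIN_SUPPORT = 4
DEFAULT_PROBE_LEN = 60
DEFAULT_TERMINUS_IDENTITY = 0.90
DEFAULT_TSD_SEARCH_WINDOW = 20


@dataclass(frozen=True)
class ClippedSegment:
    """One soft-clipped read end.

    ``clip_pos`` is the reference coordinate (0-based) of the first or
    last aligned base adjacent to the clip; ``side`` is ``left`` when
    the clip precedes the alignment and ``right`` when it follows it.
    """

    read_id: str
    replicon_id: str
    clip_pos: int
    side: str
    clip_seq: str


@dataclass(frozen=True)
class SoftClipCluster:
    """Clips of one side piled at one reference position."""

    replicon_id: str
    position: int
    side: str
    support: int
    consensus_clip: str
    matched_is: tuple[str, str, float] | None = None  # (is_name, terminus, identity)


@dataclass(frozen=True)
class InsertionCall:
    """One inferred insertion site on the reference.

    ``start``/``end`` bracket the insertion point (0-based, inclusive
    of both flank boundary coordinates); ``tsd_len`` is the inferred
    target-site duplication, 0 when none was resolved.
    """

    replicon_id: str
    start: int
    end: int
    is_name: str
    left_support: int
    right_support: int
    tsd_len: int = 0
    single_flank: bool = False
    status_per_sample: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")


def extract_softclips(
    path: str,
    min_clip_len: int = DEFAULT_MIN_CLIP_LEN,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> list[ClippedSegment]:
    """Soft-clipped read ends from a coordinate-sorted SAM/BAM file.

    One segment per qualifying clipped end (length >= min_clip_len on a
    primary alignment with MAPQ >= min_mapq).  Reads with identical
    (position, CIGAR, sequence) count once, so PCR duplicates do not
    inflate support.  Raises on coordinate-unsorted input and on
    records without a sequence field.
    """
    out: list[ClippedSegment] = []
    seen: set[tuple] = set()
    last: dict[int, int] = {}
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_start < last.get(read.reference_id, 0):
                raise ValueError("input alignments are not coordinate-sorted")
            last[read.reference_id] = read.reference_start
            if read.mapping_quality < min_mapq:
                continue
            cig = read.cigartuples
            if cig is None or not any(op == 4 for op, _ in cig):
                continue
            seq = read.query_sequence
            if seq is None:
                raise ValueError(f"read {read.query_name} has no sequence field")
            key = (read.reference_id, read.reference_start, read.cigarstring, seq)
            if key in seen:
                continue
            seen.add(key)
            rname = read.reference_name
            if cig[0][0] == 4 and cig[0][1] >= min_clip_len:
                out.append(
                    ClippedSegment(
                        read.query_name, rname, read.reference_start, "left",
                        seq[: cig[0][1]],
                    )
                )
            if cig[-1][0] == 4 and cig[-1][1] >= min_clip_len:
                out.append(
                    ClippedSegment(
                        read.query_name, rname, read.reference_end - 1, "right",
                        seq[len(seq) - cig[-1][1] :],
                    )
                )
    return out


def _column_consensus(seqs: list[str], anchor: str, max_len: int) -> str:
    """Majority-vote consensus of clip sequences anchored at the junction.

    Right-side clips share their first base (the junction edge), so they
    are anchored left; left-side clips share their last base and are
    anchored right.
    """
    if anchor == "right":
        seqs = [s[::-1] for s in seqs]
    length = min(max(len(s) for s in seqs), max_len)
    cols = []
    for i in range(length):
        counts = Counter(s[i] for s in seqs if len(s) > i)
        if not counts:
            break
        cols.append(max(sorted(counts), key=counts.get))
    cons = "".join(cols)
    return cons[::-1] if anchor == "right" else cons


def match_termini(
    consensus_clip: str,
    rec: ISRecord,
    min_identity: float = DEFAULT_TERMINUS_IDENTITY,
    probe_len: int = DEFAULT_PROBE_LEN,
) -> tuple[str, str, float] | None:
    """Match a clip consensus against the termini of an IS consensus.

    The clip is compared, gaplessly, against the first and last
    ``probe_len`` bp of the consensus and of its reverse complement,
    anchored at the junction-facing end.  Returns (is_name, terminus,
    identity) for the best terminus at identity >= min_identity, or
    None.  Termini are ``5prime``/``3prime`` of the element regardless
    of its insertion orientation.
    """
    if len(consensus_clip) < 12:
        raise ValueError("clip consensus must be >= 12 bp")
    cons = rec.consensus_seq
    rc = revcomp(cons)
    candidates = [
        ("5prime", cons[:probe_len], "left"),    # clip reads into the element 5' end
        ("3prime", rc[:probe_len], "left"),      # reverse-oriented insert, right junction
        ("3prime", cons[-probe_len:], "right"),  # clip ends at the element 3' end
        ("5prime", rc[-probe_len:], "right"),
    ]
    best: tuple[str, str, float] | None = None
    for terminus, probe, anchor in candidates:
        n = min(len(consensus_clip), len(probe))
        if n < 12:
            continue
        if anchor == "left":
            a, b = consensus_clip[:n], probe[:n]
        else:
            a, b = consensus_clip[-n:], probe[-n:]
        matches = sum(1 for x, y in zip(a, b) if x == y and x in "ACGT")
        ident = matches / n
        if ident >= min_identity and (best is None or ident > best[2]):
            best = (rec.name, terminus, ident)
    return best


def cluster_softclips(
    segments: list[ClippedSegment],
    catalog: list[ISRecord],
    cluster_window: int = DEFAULT_CLUSTER_WINDOW,
    probe_len: int = DEFAULT_PROBE_LEN,
    min_identity: float = DEFAULT_TERMINUS_IDENTITY,
) -> list[SoftClipCluster]:
    """Group clips by (replicon, side, position) and match IS termini."""
    groups: dict[tuple[str, str], list[ClippedSegment]] = {}
    for seg in segments:
        groups.setdefault((seg.replicon_id, seg.side), []).append(seg)
    clusters: list[SoftClipCluster] = []
    for (replicon_id, side), segs in sorted(groups.items()):
        segs.sort(key=lambda s: s.clip_pos)
        bucket: list[ClippedSegment] = []
        for seg in segs:
            if bucket and seg.clip_pos - bucket[0].clip_pos > cluster_window:
                clusters.append(
                    _finish_cluster(bucket, replicon_id, side, catalog, probe_len, min_identity)
                )
                bucket = []
            bucket.append(seg)
        if bucket:
            clusters.append(
                _finish_cluster(bucket, replicon_id, side, catalog, probe_len, min_identity)
            )
    return clusters


def _finish_cluster(bucket, replicon_id, side, catalog, probe_len, min_identity):
    positions = Counter(s.clip_pos for s in bucket)
    position = max(sorted(positions), key=positions.get)
    cons = _column_consensus(
        [s.clip_seq for s in bucket],
        anchor="left" if side == "right" else "right",
        max_len=probe_len,
    )
    matched = None
    if len(cons) >= 12:
        for rec in catalog:
            m = match_termini(cons, rec, min_identity=min_identity, probe_len=probe_len)
            if m is not None and (matched is None or m[2] > matched[2]):
                matched = m
    return SoftClipCluster(replicon_id, position, side, len(bucket), cons, matched)


def call_insertions(
    segments: list[ClippedSegment],
    catalog: list[ISRecord],
    cluster_window: int = DEFAULT_CLUSTER_WINDOW,
    min_support: int = DEFAULT_MIN_SUPPORT,
    tsd_search_window: int = DEFAULT_TSD_SEARCH_WINDOW,
    probe_len: int = DEFAULT_PROBE_LEN,
    min_identity: float = DEFAULT_TERMINUS_IDENTITY,
) -> list[InsertionCall]:
    """Pair terminus-matched clip clusters into insertion calls.

    A call needs a left-side and a right-side cluster of the same IS
    within ``tsd_search_window`` bp (each with support >= min_support),
    or a single flank with support >= 2 * min_support (flagged).  The
    paired flank offset yields ``tsd_len``.
    """
    clusters = [
        c
        for c in cluster_softclips(
            segments, catalog, cluster_window, probe_len, min_identity
        )
        if c.matched_is is not None and c.support >= min_support
    ]
    calls: list[InsertionCall] = []
    used: set[int] = set()
    by_replicon: dict[str, list[tuple[int, SoftClipCluster]]] = {}
    for idx, c in enumerate(clusters):
        by_replicon.setdefault(c.replicon_id, []).append((idx, c))
    for replicon_id, items in sorted(by_replicon.items()):
        lefts = [(i, c) for i, c in items if c.side == "left"]
        rights = [(i, c) for i, c in items if c.side == "right"]
        for li, lc in lefts:
            best = None
            for ri, rc_ in rights:
                if ri in used or rc_.matched_is[0] != lc.matched_is[0]:
                    continue
                offset = rc_.position - lc.position
                if -1 <= offset <= tsd_search_window:
                    if best is None or abs(offset) < abs(best[1]):
                        best = (ri, offset, rc_)
            if best is not None:
                ri, offset, rc_ = best
                used.update((li, ri))
                calls.append(
                    InsertionCall(
                        replicon_id=replicon_id,
                        start=min(lc.position, rc_.position),
                        end=max(lc.position, rc_.position),
                        is_name=lc.matched_is[0],
                        left_support=lc.support,
                        right_support=rc_.support,
                        tsd_len=max(0, offset + 1),
                    )
                )
        for i, c in items:
            if i in used or c.support < 2 * min_support:
                continue
            used.add(i)
            calls.append(
                InsertionCall(
                    replicon_id=replicon_id,
                    start=c.position,
                    end=c.position,
                    is_name=c.matched_is[0],
                    left_support=c.support if c.side == "left" else 0,
                    right_support=c.support if c.side == "right" else 0,
                    tsd_len=0,
                    single_flank=True,
                )
            )
    calls.sort(key=lambda c: (c.replicon_id, c.start))
    return calls


@dataclass
class PresenceMatrix:
    """Candidate sites x samples presence/absence table."""

    table: pd.DataFrame  # columns: replicon_id, start, end, reference, <samples...>
    samples: tuple[str, ...]

    def novel_counts(self, replicon_id: str | None = None) -> dict[str, int]:
        """Sites absent from the reference but present in each sample."""
        t = self.table
        if replicon_id is not None:
            t = t[t.replicon_id == replicon_id]
        novel = t[t.reference == "NO"]
        return {s: int((novel[s] == "YES").sum()) for s in self.samples}

    def shared_novel(self, sample_a: str, sample_b: str, replicon_id: str | None = None) -> int:
        t = self.table
        if replicon_id is not None:
            t = t[t.replicon_id == replicon_id]
        novel = t[t.reference == "NO"]
        return int(((novel[sample_a] == "YES") & (novel[sample_b] == "YES")).sum())


def compare_samples(
    reference_loci: list[ISLocus],
    calls_by_sample: dict[str, list[InsertionCall]],
    cluster_window: int = DEFAULT_CLUSTER_WINDOW,
) -> PresenceMatrix:
    """Merge reference loci and per-sample calls into a presence matrix.

    Sites whose start coordinates lie within ``cluster_window`` on the
    same replicon collapse into one row.  The reference column derives
    from the reference loci; sample columns from the calls.
    """
    samples = tuple(sorted(calls_by_sample))
    entries: list[tuple[str, int, int, str]] = []
    for locus in reference_loci:
        entries.append((locus.replicon_id, locus.start, locus.end, "reference"))
    for sample, calls in calls_by_sample.items():
        for c in calls:
            entries.append((c.replicon_id, c.start, c.end, sample))
    entries.sort(key=lambda e: (e[0], e[1]))
    rows = []
    current: dict | None = None
    for replicon_id, start, end, origin in entries:
        if (
            current is None
            or replicon_id != current["replicon_id"]
            or start - current["anchor"] > cluster_window
        ):
            if current is not None:
                rows.append(current)
            current = {
                "replicon_id": replicon_id,
                "anchor": start,
                "start": start,
                "end": end,
                "origins": set(),
            }
        current["end"] = max(current["end"], end)
        current["origins"].add(origin)
    if current is not None:
        rows.append(current)
    table = pd.DataFrame(
        [
            {
                "replicon_id": r["replicon_id"],
                "start": r["start"],
                "end": r["end"],
                "reference": "YES" if "reference" in r["origins"] else "NO",
                **{s: "YES" if s in r["origins"] else "NO" for s in samples},
            }
            for r in rows
        ],
        columns=["replicon_id", "start", "end", "reference", *samples],
    )
    return PresenceMatrix(table, samples)
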
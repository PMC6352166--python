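"""Similarity search of IS consensus sequences against replicons.

Two search levels mirror the two thresholds used for IS annotation in
*Thermus* genomes: a nucleotide scan that reports local alignments at
>= 80% identity, and a translated scan that compares the six-frame
translation of the replicon against reference transposase proteins at
>= 30% amino-acid identity.

Both levels are self-contained seed-and-extend searches: exact k-mer
seeds on both strands, a cheap ungapped x-drop extension to discard
chance seeds, then full affine-gap Smith-Waterman restricted to the
candidate window.  Because the windowed extension runs the exact same
dynamic program as :func:`sw_oracle`, the seeded search is testable
against the exhaustive oracle; only hits whose identity sits within a
couple of points of the threshold can be lost to seeding.

Nucleotide scoring defaults to +2/-3 with -5/-2 gaps.  Protein scoring
defaults to the milder +2/-1 with -4/-1 gaps so that distant but
full-length transposase homologies (down to ~1/3 identity) retain a
positive score per column and survive as single local alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

from Bio.Seq import Seq

from .align import (
    LocalAlignment,
    Scoring,
    encode_dna,
    encode_protein,
    local_align_all,
    revcomp,
)
from .catalog import ISRecord, Replicon


@dataclass(frozen=True)
class SearchConfig:
    """Thresholds and scoring for both search levels."""

    nt_identity_min: float = 0.80
    aa_identity_min: float = 0.30
    seed_len: int = 12
    aa_seed_len: int = 5
    x_drop: int = 20
    min_hit_len: int = 50
    min_aa_hit_len: int = 50
    nt_scoring: Scoring = field(default_factory=Scoring)
    aa_scoring: Scoring = field(
        default_factory=lambda: Scoring(match=2, mismatch=-1, gap_open=-4, gap_extend=-1)
    )
    #: minimum ungapped extension score for a seed to open a DP window.
    seed_filter_score: int = 30
    max_hits_per_window: int = 50
    #: subjects at most this long are mined whole once any seed fires,
    #: making the seeded search exactly oracle-equivalent at that scale;
    #: longer subjects use padded candidate windows (heuristic).
    full_mine_max: int = 2048

    def __post_init__(self) -> None:
        if not 0 < self.nt_identity_min <= 1:
            raise ValueError("nt_identity_min must be in (0, 1]")
        if not 0 < self.aa_identity_min <= 1:
            raise ValueError("aa_identity_min must be in (0, 1]")
        if self.seed_len < 8:
            raise ValueError("seed_len must be >= 8")

    def min_dp_score(self, level: str) -> int:
        """Lowest DP score a qualifying alignment can have.

        A hit must span >= min_hit_len columns at identity >= the
        threshold, so (counting the harsher of mismatch and gap-open as
        the per-column penalty) its score is at least
        ``min_len * (ident * match + (1 - ident) * worst)``.  When that
        bound is non-positive (permissive thresholds), alignment mining
        falls back to half the all-match score of a minimal hit; weaker
        alignments are below the mining horizon of both the seeded
        search and the oracle.
        """
        if level == "nucleotide":
            ident, min_len, sc = self.nt_identity_min, self.min_hit_len, self.nt_scoring
        else:
            ident, min_len, sc = self.aa_identity_min, self.min_aa_hit_len, self.aa_scoring
        worst = min(sc.mismatch, sc.gap_open)
        floor = min_len * (ident * sc.match + (1 - ident) * worst)
        if floor >= 1:
            return ceil(floor)
        return max(1, ceil(min_len * ident * sc.match / 2))


@dataclass(frozen=True)
class Hit:
    """One local alignment of a catalog IS against a replicon.

    ``start``/``end`` are 0-based half-open replicon coordinates.
    ``q_start``/``q_end`` give the aligned query interval: consensus
    coordinates for nucleotide hits, reference-protein amino-acid
    coordinates for translated hits.  ``is_cov`` is the fraction of the
    IS consensus covered by the alignment.
    """

    is_name: str
    replicon_id: str
    start: int
    end: int
    strand: str
    identity: float
    is_cov: float
    level: str
    score: int
    q_start: int
    q_end: int
    ref_name: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("bad hit interval")
        if not 0 <= self.identity <= 1:
            raise ValueError("identity outside [0, 1]")


def sw_oracle(
    query: str,
    subject: str,
    scoring: Scoring,
    min_score: int,
    alphabet: str = "dna",
    max_alignments: int = 200,
) -> list[LocalAlignment]:
    """Exhaustive local alignment of query against subject.

    Full Smith-Waterman over the whole subject (no seeding), enumerating
    subject-disjoint alignments best-score first.  Refuses instances
    with more than 4e6 matrix cells.  Serves as the independent oracle
    for the seeded searches.
    """
    if len(query) * len(subject) > 4_000_000:
        raise ValueError("oracle instance too large (> 4e6 cells)")
    enc = encode_dna if alphabet == "dna" else encode_protein
    return local_align_all(enc(query), enc(subject), scoring, min_score, max_alignments)


def _seed_windows(
    q_enc, s_enc, k: int, scoring: Scoring, x_drop: int, filter_score: int,
    full_mine_max: int = 0,
):
    """Candidate subject windows from exact k-mer seeds.

    Seeds are grouped per diagonal; each undergoes ungapped x-drop
    extension, and extensions scoring >= filter_score project a subject
    window wide enough to hold any alignment of the full query plus gap
    slack.  Overlapping windows are merged.
    """
    n, m = len(q_enc), len(s_enc)
    if n < k or m < k:
        return []
    index: dict[bytes, list[int]] = {}
    s_bytes = s_enc.tobytes()
    for j in range(m - k + 1):
        kmer = s_bytes[j : j + k]
        index.setdefault(kmer, []).append(j)
    q_bytes = q_enc.tobytes()

    covered: dict[int, int] = {}  # diagonal -> subject pos already extended through
    windows: list[list[int]] = []
    slack = max(50, n // 10)
    for i in range(n - k + 1):
        kmer = q_bytes[i : i + k]
        if bytes([AMBIG]) in kmer or bytes([201]) in kmer:
            continue
        for j in index.get(kmer, ()):
            diag = j - i
            if covered.get(diag, -1) >= j:
                continue
            score, s_lo, s_hi, q_lo = _ungapped_extend(
                q_enc, s_enc, i, j, k, scoring, x_drop
            )
            covered[diag] = s_hi
            if score >= filter_score:
                lo = max(0, s_lo - q_lo - slack)
                hi = min(m, s_hi + (n - (q_lo + (s_hi - s_lo))) + slack)
                windows.append([lo, hi])
    if not windows:
        return []
    if m <= full_mine_max:
        return [(0, m)]
    windows.sort()
    merged = [windows[0]]
    for lo, hi in windows[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


AMBIG = 200


def _ungapped_extend(q, s, i, j, k, scoring: Scoring, x_drop: int):
    """X-drop ungapped extension of a seed; returns (score, s_lo, s_hi, q_lo)."""
    match, mismatch = scoring.match, scoring.mismatch
    score = k * match
    best = score
    # right
    qi, sj = i + k, j + k
    bq, bs = qi, sj
    while qi < len(q) and sj < len(s):
        if q[qi] == s[sj] and q[qi] < AMBIG:
            score += match
        else:
            score += mismatch
        qi += 1
        sj += 1
        if score > best:
            best, bq, bs = score, qi, sj
        if best - score > x_drop:
            break
    right_q, right_s = bq, bs
    # left
    score = best
    qi, sj = i - 1, j - 1
    bq, bs = i, j
    while qi >= 0 and sj >= 0:
        if q[qi] == s[sj] and q[qi] < AMBIG:
            score += match
        else:
            score += mismatch
        if score > best:
            best, bq, bs = score, qi, sj
        qi -= 1
        sj -= 1
        if best - score > x_drop:
            break
    return best, bs, right_s, bq


def _hits_from_alignments(
    alns: list[LocalAlignment],
    rec_name: str,
    replicon: Replicon,
    strand: str,
    q_len: int,
    cons_len: int,
    level: str,
    ident_min: float,
    min_len: int,
    s_offset: int = 0,
    ref_name: str | None = None,
) -> list[Hit]:
    hits = []
    for a in alns:
        if a.columns < min_len or a.identity < ident_min:
            continue
        if strand == "+" or level == "translated":
            q_start, q_end = a.q_start, a.q_end
        else:  # query was reverse-complemented; map back to consensus coords
            q_start, q_end = q_len - a.q_end, q_len - a.q_start
        hits.append(
            Hit(
                is_name=rec_name,
                replicon_id=replicon.id,
                start=s_offset + a.s_start,
                end=s_offset + a.s_end,
                strand=strand,
                identity=a.identity,
                is_cov=(q_end - q_start) * (3 if level == "translated" else 1) / cons_len,
                level=level,
                score=a.score,
                q_start=q_start,
                q_end=q_end,
                ref_name=ref_name,
            )
        )
    return hits


def search_nt(replicon: Replicon, rec: ISRecord, cfg: SearchConfig | None = None) -> list[Hit]:
    """Nucleotide-level search of one IS consensus against one replicon.

    Reports every maximal local alignment at identity >= nt_identity_min
    spanning >= min_hit_len columns, on either strand, sorted by start.
    """
    cfg = cfg or SearchConfig()
    if not replicon.seq or not rec.consensus_seq:
        raise ValueError("replicon and consensus must be non-empty")
    s_enc = encode_dna(replicon.seq)
    min_score = cfg.min_dp_score("nucleotide")
    hits: list[Hit] = []
    for strand, qseq in (("+", rec.consensus_seq), ("-", revcomp(rec.consensus_seq))):
        q_enc = encode_dna(qseq)
        for lo, hi in _seed_windows(
            q_enc, s_enc, cfg.seed_len, cfg.nt_scoring, cfg.x_drop,
            cfg.seed_filter_score, cfg.full_mine_max,
        ):
            alns = local_align_all(
                q_enc, s_enc[lo:hi], cfg.nt_scoring, min_score, cfg.max_hits_per_window
            )
            hits.extend(
                _hits_from_alignments(
                    alns, rec.name, replicon, strand, len(qseq), rec.length,
                    "nucleotide", cfg.nt_identity_min, cfg.min_hit_len, s_offset=lo,
                )
            )
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def _frames(seq: str):
    """Six-frame translation with coordinate bookkeeping.

    Yields (strand, offset, protein); protein index ``a`` corresponds to
    forward-strand nucleotides ``offset + 3a .. offset + 3a + 3`` on '+'
    and ``L - offset - 3a - 3 .. L - offset - 3a`` on '-'.
    """
    fwd = Seq(seq)
    rev = fwd.reverse_complement()
    for strand, s in (("+", fwd), ("-", rev)):
        for offset in range(3):
            trimmed = s[offset : offset + 3 * ((len(s) - offset) // 3)]
            yield strand, offset, str(trimmed.translate(table=11))


def search_translated(
    replicon: Replicon, rec: ISRecord, cfg: SearchConfig | None = None
) -> list[Hit]:
    """Translated search: replicon six-frame vs reference transposases.

    Hits are reported in nucleotide coordinates of the replicon with the
    strand of the matching frame; the aligned query interval is in
    amino acids of the reference protein.  Translation table 11.
    """
    cfg = cfg or SearchConfig()
    if not rec.transposase_refs:
        raise ValueError(f"{rec.name}: no transposase reference proteins")
    min_score = cfg.min_dp_score("translated")
    L = replicon.length_bp
    hits: list[Hit] = []
    for strand, offset, prot in _frames(replicon.seq):
        s_enc = encode_protein(prot)
        for ref in rec.transposase_refs:
            q_enc = encode_protein(ref.seq)
            for lo, hi in _seed_windows(
                q_enc, s_enc, cfg.aa_seed_len, cfg.aa_scoring, cfg.x_drop,
                cfg.seed_filter_score,
            ):
                alns = local_align_all(
                    q_enc, s_enc[lo:hi], cfg.aa_scoring, min_score, cfg.max_hits_per_window
                )
                for a in alns:
                    if a.columns < cfg.min_aa_hit_len or a.identity < cfg.aa_identity_min:
                        continue
                    aa_lo, aa_hi = lo + a.s_start, lo + a.s_end
                    if strand == "+":
                        nt_start = offset + 3 * aa_lo
                        nt_end = offset + 3 * aa_hi
                    else:
                        nt_end = L - offset - 3 * aa_lo
                        nt_start = L - offset - 3 * aa_hi
                    hits.append(
                        Hit(
                            is_name=rec.name,
                            replicon_id=replicon.id,
                            start=nt_start,
                            end=nt_end,
                            strand=strand,
                            identity=a.identity,
                            is_cov=min(1.0, 3 * (a.q_end - a.q_start) / rec.length),
                            level="translated",
                            score=a.score,
                            q_start=a.q_start,
                            q_end=a.q_end,
                            ref_name=ref.name,
                        )
                    )
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits
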
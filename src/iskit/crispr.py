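"""Separate IS-derived CRISPR repeat arrays from genuine IS scars.

In *Thermus thermophilus* a 32 bp internal segment of the IS1000A/B
element has been recruited as the repeat unit of CRISPR arrays: tandem
copies separated by 30-40 bp unique spacers.  A naive IS scan counts
every array copy as a partial IS fragment, grossly inflating scar
counts.  This module finds all copies of such a repeat, chains tandem
copies whose spacing matches the CRISPR geometry into arrays, and
removes partial IS loci lying inside an array from the IS tally.
Isolated copies of the same repeat (outside any array) remain genuine
IS fragments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import revcomp
from .catalog import ISRecord, Replicon
from .loci import ISLocus

DEFAULT_SPACER_MIN = 30
DEFAULT_SPACER_MAX = 40
DEFAULT_MIN_ARRAY_COPIES = 3


@dataclass(frozen=True)
class RepeatArray:
    """A tandem array of a short repeat (positions 0-based, forward strand)."""

    repeat_seq: str
    replicon_id: str
    strand: str
    copy_positions: tuple[int, ...]
    spacer_lengths: tuple[int, ...]
    classification: str  # crispr_array | isolated_fragment

    def __post_init__(self) -> None:
        if list(self.copy_positions) != sorted(set(self.copy_positions)):
            raise ValueError("copy positions must be strictly increasing")
        if len(self.spacer_lengths) != max(0, len(self.copy_positions) - 1):
            raise ValueError("need one spacer length per adjacent copy pair")

    @property
    def n_copies(self) -> int:
        return len(self.copy_positions)

    @property
    def span(self) -> tuple[int, int]:
        return self.copy_positions[0], self.copy_positions[-1] + len(self.repeat_seq)


def extract_repeat(rec: ISRecord, start: int, end: int) -> str:
    """Substring of the consensus by 1-based inclusive coordinates."""
    if not 1 <= start <= end <= rec.length:
        raise ValueError(
            f"coordinates [{start}, {end}] outside consensus of length {rec.length}"
        )
    return rec.consensus_seq[start - 1 : end]


def find_repeat_copies(
    replicon: Replicon, repeat: str, max_mismatch: int = 0
) -> list[tuple[int, str]]:
    """All gapless occurrences of the repeat on either strand.

    Returns (start, strand) pairs sorted by position; matching is a
    sliding Hamming comparison where N never matches.
    """
    if len(repeat) < 16:
        raise ValueError("repeat must be >= 16 bp")
    out: list[tuple[int, str]] = []
    for strand, probe in (("+", repeat), ("-", revcomp(repeat))):
        out.extend((pos, strand) for pos in _scan(replicon.seq, probe, max_mismatch))
    out.sort()
    return out


def _scan(seq: str, probe: str, max_mismatch: int) -> list[int]:
    k = len(probe)
    if len(seq) < k:
        return []
    if max_mismatch == 0 and "N" not in probe:
        hits, idx = [], seq.find(probe)
        while idx >= 0:
            hits.append(idx)
            idx = seq.find(probe, idx + 1)
        return hits
    s = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    p = np.frombuffer(probe.encode("ascii"), dtype=np.uint8)
    n_mask = (s == ord("N")).astype(np.int32)
    mism = np.zeros(len(seq) - k + 1, dtype=np.int32)
    for off in range(k):
        col = s[off : off + len(mism)]
        mism += (col != p[off]).astype(np.int32) | n_mask[off : off + len(mism)]
    return np.flatnonzero(mism <= max_mismatch).tolist()


def cluster_arrays(
    positions: list[tuple[int, str]],
    repeat_seq: str,
    replicon_id: str,
    spacer_min: int = DEFAULT_SPACER_MIN,
    spacer_max: int = DEFAULT_SPACER_MAX,
    min_array_copies: int = DEFAULT_MIN_ARRAY_COPIES,
) -> list[RepeatArray]:
    """Chain tandem copies into arrays by the spacer-length rule.

    Consecutive same-strand copies chain when the gap between them
    (start difference minus repeat length) lies in
    [spacer_min, spacer_max]; chains of >= min_array_copies copies are
    CRISPR arrays, smaller ones isolated fragments.  Every detected
    copy belongs to exactly one array object.
    """
    if list(positions) != sorted(positions):
        raise ValueError("positions must be sorted")
    k = len(repeat_seq)
    arrays: list[RepeatArray] = []
    for strand in ("+", "-"):
        chain: list[int] = []
        for pos in [p for p, s in positions if s == strand]:
            if chain and spacer_min <= pos - chain[-1] - k <= spacer_max:
                chain.append(pos)
            else:
                if chain:
                    arrays.append(_make_array(chain, repeat_seq, replicon_id, strand, min_array_copies))
                chain = [pos]
        if chain:
            arrays.append(_make_array(chain, repeat_seq, replicon_id, strand, min_array_copies))
    arrays.sort(key=lambda a: a.copy_positions[0])
    return arrays


def _make_array(chain, repeat_seq, replicon_id, strand, min_array_copies) -> RepeatArray:
    spacers = tuple(b - a - len(repeat_seq) for a, b in zip(chain, chain[1:]))
    cls = "crispr_array" if len(chain) >= min_array_copies else "isolated_fragment"
    return RepeatArray(repeat_seq, replicon_id, strand, tuple(chain), spacers, cls)


def reconcile(
    loci: list[ISLocus], arrays: list[RepeatArray], margin: int = 20
) -> tuple[list[ISLocus], list[tuple[ISLocus, RepeatArray]]]:
    """Drop partial IS loci that are really CRISPR repeats.

    A partial locus whose span lies within a crispr_array span
    (allowing ``margin`` bp of alignment jitter at either edge) is
    excluded from the IS tally and logged with the array that absorbed
    it; complete loci and copies outside arrays are never touched.
    Returns (kept loci, exclusion log).
    """
    crispr = [a for a in arrays if a.classification == "crispr_array"]
    kept: list[ISLocus] = []
    excluded: list[tuple[ISLocus, RepeatArray]] = []
    for locus in loci:
        absorber = None
        if locus.status == "partial":
            for arr in crispr:
                if arr.replicon_id != locus.replicon_id:
                    continue
                lo, hi = arr.span
                if lo - margin <= locus.start and locus.end <= hi + margin:
                    absorber = arr
                    break
        if absorber is None:
            kept.append(locus)
        else:
            excluded.append((locus, absorber))
    return kept, excluded
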
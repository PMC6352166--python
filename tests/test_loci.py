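"""Locus assembly, completeness, TSD and IR detection."""

import numpy as np
import pytest

from iskit.align import revcomp
from iskit.catalog import Replicon
from iskit.loci import (
    ISLocus,
    build_loci,
    classify_completeness,
    detect_ir,
    detect_tsd,
    merge_hits,
)
from iskit.search import Hit, search_nt
from iskit.simulate import random_dna, synth_is_record

from .oracles import interval_union_len


@pytest.fixture(scope="module")
def rec():
    return synth_is_record(np.random.default_rng(11), "ISx", length_range=(900, 1150))


def _hit(rec, start, end, q_start, q_end, strand="+"):
    return Hit(
        is_name=rec.name,
        replicon_id="chr",
        start=start,
        end=end,
        strand=strand,
        identity=1.0,
        is_cov=(q_end - q_start) / rec.length,
        level="nucleotide",
        score=2 * (q_end - q_start),
        q_start=q_start,
        q_end=q_end,
    )


def test_merge_abutting_hits_full_coverage(rec):
    """Two hits partitioning the consensus merge into one full locus."""
    L = rec.length
    hits = [_hit(rec, 1000, 1600, 0, 600), _hit(rec, 1600, 1000 + L, 600, L)]
    (locus,) = merge_hits(hits, {rec.name: rec})
    assert locus.coverage == 1.0
    assert (locus.start, locus.end) == (1000, 1000 + L)


def test_single_partial_hit_coverage(rec):
    frag = int(0.4 * rec.length)
    (locus,) = merge_hits([_hit(rec, 500, 500 + frag, 0, frag)], {rec.name: rec})
    assert locus.coverage == pytest.approx(0.4, abs=0.01)


@pytest.mark.parametrize("trial", range(20))
def test_fragmented_copy_coverage_matches_union_oracle(rec, trial):
    """Random <=5-piece fragmentations: coverage equals bitmap interval union."""
    rng = np.random.default_rng(500 + trial)
    L = rec.length
    cuts = sorted(rng.choice(np.arange(50, L - 50), size=int(rng.integers(1, 5)), replace=False))
    pieces = [(a, b) for a, b in zip([0, *cuts], [*cuts, L]) if b - a >= 50]
    hits, pos = [], 2000
    for a, b in pieces:
        hits.append(_hit(rec, pos, pos + (b - a), a, b))
        pos += (b - a) + int(rng.integers(0, 51))  # gaps <= 50 bp chain together
    (locus,) = merge_hits(hits, {rec.name: rec})
    assert locus.coverage == pytest.approx(
        interval_union_len(pieces, L) / L, abs=1e-9
    )


def test_distant_hits_stay_separate(rec):
    hits = [_hit(rec, 0, 400, 0, 400), _hit(rec, 2000, 2400, 0, 400)]
    loci = merge_hits(hits, {rec.name: rec})
    assert len(loci) == 2


def test_completeness_rules(rec):
    lo, hi = rec.length_range

    def locus(cov, length):
        return ISLocus(rec.name, "chr", 0, length, "+", coverage=cov)

    assert classify_completeness(locus(1.0, rec.length), rec) == "complete"
    assert classify_completeness(locus(0.95, rec.length), rec) == "complete"  # inclusive
    assert classify_completeness(locus(0.9499, rec.length), rec) == "partial"
    assert classify_completeness(locus(0.40, int(0.4 * rec.length)), rec) == "partial"
    assert classify_completeness(locus(1.0, int(0.8 * lo)), rec) == "partial"  # too short
    assert classify_completeness(locus(1.0, int(1.2 * hi)), rec) == "partial"  # too long


def test_tsd_detection(rec):
    """Identical flanks of DR length are called; differing or absent ones not."""
    rng = np.random.default_rng(3)
    tsd = "GCCTTAAC"
    bg = random_dna(rng, 5000)
    seq = bg[:2000] + tsd + rec.consensus_seq + tsd + bg[2000:]
    rep = Replicon("chr", "chromosome", seq)
    locus = ISLocus(rec.name, "chr", 2008, 2008 + rec.length, "+", coverage=1.0)
    assert detect_tsd(rep, locus, rec) == (tsd, False)
    # one flank off by a base
    broken = seq[:2000] + "A" + seq[2001:]
    assert detect_tsd(Replicon("chr", "chromosome", broken), locus, rec)[0] is None
    # dr_len = 0 records never have a TSD
    from dataclasses import replace

    assert detect_tsd(rep, locus, replace(rec, dr_len=0)) == (None, False)
    # locus at the replicon edge is flagged
    edge_rep = Replicon("chr", "chromosome", rec.consensus_seq + bg[:100])
    edge_locus = ISLocus(rec.name, "chr", 0, rec.length, "+", coverage=1.0)
    assert detect_tsd(edge_rep, edge_locus, rec) == (None, True)


def test_ir_evidence(rec):
    rng = np.random.default_rng(4)
    bg = random_dna(rng, 4000)
    seq = bg[:1000] + rec.consensus_seq + bg[1000:]
    rep = Replicon("chr", "chromosome", seq)
    full = ISLocus(rec.name, "chr", 1000, 1000 + rec.length, "+", coverage=1.0)
    assert detect_ir(rep, full, rec) == "both"
    # 5'-truncated copy retains only the right terminus
    cut = 200
    seq2 = bg[:1000] + rec.consensus_seq[cut:] + bg[1000:]
    trunc = ISLocus(rec.name, "chr", 1000, 1000 + rec.length - cut, "+", coverage=0.8)
    assert detect_ir(Replicon("chr", "chromosome", seq2), trunc, rec) == "right"
    # randomized termini: no evidence
    middle = rec.consensus_seq[50:-50]
    seq3 = bg[:1000] + random_dna(rng, 50) + middle + random_dna(rng, 50) + bg[1000:]
    rand = ISLocus(rec.name, "chr", 1000, 1000 + rec.length, "+", coverage=0.9)
    assert detect_ir(Replicon("chr", "chromosome", seq3), rand, rec) == "none"


def test_minus_strand_ir_and_tsd(rec):
    """TSD/IR logic is orientation-aware for minus-strand copies."""
    rng = np.random.default_rng(5)
    bg = random_dna(rng, 4000)
    tsd = random_dna(rng, rec.dr_len)
    seq = bg[:1500] + tsd + revcomp(rec.consensus_seq) + tsd + bg[1500:]
    rep = Replicon("chr", "chromosome", seq)
    locus = ISLocus(
        rec.name, "chr", 1500 + rec.dr_len, 1500 + rec.dr_len + rec.length, "-", coverage=1.0
    )
    assert detect_tsd(rep, locus, rec)[0] == tsd
    assert detect_ir(rep, locus, rec) == "both"


def test_planted_copies_recovered_exactly(rec):
    """k verbatim copies with TSDs give k complete loci at exact coordinates."""
    rng = np.random.default_rng(6)
    bg = random_dna(rng, 30_000)
    positions = [3_000, 12_000, 21_000]
    seq, shift, truth = bg, 0, []
    for p in positions:
        tsd = random_dna(rng, rec.dr_len)
        ins = tsd + rec.consensus_seq + tsd
        seq = seq[: p + shift] + ins + seq[p + shift :]
        truth.append(p + shift + rec.dr_len)
        shift += len(ins)
    rep = Replicon("chr", "chromosome", seq)
    loci = build_loci(rep, search_nt(rep, rec), [rec])
    assert [(l.start, l.end, l.status) for l in loci] == [
        (t, t + rec.length, "complete") for t in truth
    ]
    assert all(l.tsd_seq is not None and l.ir_evidence == "both" for l in loci)


def test_truncated_copy_is_partial(rec):
    """A copy below the coverage threshold is always a scar."""
    rng = np.random.default_rng(7)
    frag = rec.consensus_seq[: int(0.6 * rec.length)]
    rep = Replicon("chr", "chromosome", random_dna(rng, 10_000)[:4000] + frag + random_dna(rng, 4000))
    loci = build_loci(rep, search_nt(rep, rec), [rec])
    assert len(loci) == 1
    assert loci[0].status == "partial"
    assert loci[0].coverage < 0.95
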
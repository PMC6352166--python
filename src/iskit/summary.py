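"""Per-replicon and per-genome IS content statistics.

Aggregates reconciled loci and activity calls into the standard survey
surfaces: complete / partial / active counts per IS type and replicon,
copy density per Mbp, the fraction of each replicon occupied by IS
sequence, and GC content of IS loci vs the host replicon.  Complete
and partial copies count equally as "copies" for density.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .activity import ActivityCall
from .catalog import Replicon
from .loci import ISLocus


@dataclass(frozen=True)
class RepliconSummary:
    replicon_id: str
    kind: str
    length_bp: int
    per_is: dict  # is_name -> {"complete": int, "partial": int, "active": int}
    density: float  # copies per Mbp
    occupancy: float
    gc_is: float | None
    gc_host: float | None

    @property
    def complete(self) -> int:
        return sum(v["complete"] for v in self.per_is.values())

    @property
    def partial(self) -> int:
        return sum(v["partial"] for v in self.per_is.values())

    @property
    def active(self) -> int:
        return sum(v["active"] for v in self.per_is.values())


def density(count: int, length_bp: int) -> float:
    """IS copies per Mbp of replicon sequence."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    return count / (length_bp / 1e6)


def _gc(seq: str) -> float | None:
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return None
    return (seq.count("G") + seq.count("C")) / acgt


def occupancy_and_gc(
    loci: list[ISLocus], replicon: Replicon
) -> tuple[float, float | None, float | None]:
    """(occupied fraction, GC of IS loci, GC of the replicon).

    Occupancy is measured over the union of locus intervals, so nested
    or adjacent loci never push it past 1.  GC counts G+C over
    unambiguous bases only.
    """
    intervals = sorted((l.start, l.end) for l in loci if l.replicon_id == replicon.id)
    merged: list[list[int]] = []
    for lo, hi in intervals:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    occupied = sum(hi - lo for lo, hi in merged)
    is_seq = "".join(replicon.seq[lo:hi] for lo, hi in merged)
    return occupied / replicon.length_bp, _gc(is_seq), _gc(replicon.seq)


def summarize(
    loci: list[ISLocus],
    activity_calls: list[ActivityCall],
    replicons: list[Replicon],
) -> list[RepliconSummary]:
    """One summary per replicon; loci should already be CRISPR-reconciled."""
    by_replicon: dict[str, list[ISLocus]] = {r.id: [] for r in replicons}
    for locus in loci:
        if locus.replicon_id not in by_replicon:
            raise ValueError(f"locus references unknown replicon {locus.replicon_id!r}")
        by_replicon[locus.replicon_id].append(locus)
    active_keys = {c.locus_key for c in activity_calls if c.verdict == "active"}
    out = []
    for rep in replicons:
        per_is: dict[str, dict[str, int]] = {}
        for locus in by_replicon[rep.id]:
            slot = per_is.setdefault(
                locus.is_name, {"complete": 0, "partial": 0, "active": 0}
            )
            slot[locus.status] += 1
            if locus.key in active_keys:
                if locus.status != "complete":
                    raise ValueError("active verdict on a non-complete locus")
                slot["active"] += 1
        n_copies = sum(v["complete"] + v["partial"] for v in per_is.values())
        occ, gc_is, gc_host = occupancy_and_gc(by_replicon[rep.id], rep)
        out.append(
            RepliconSummary(
                replicon_id=rep.id,
                kind=rep.kind,
                length_bp=rep.length_bp,
                per_is=per_is,
                density=density(n_copies, rep.length_bp),
                occupancy=occ,
                gc_is=gc_is,
                gc_host=gc_host,
            )
        )
    return out


def summary_frame(summaries: list[RepliconSummary]) -> pd.DataFrame:
    """Long-form table: one row per (replicon, IS type)."""
    rows = []
    for s in summaries:
        for is_name, v in sorted(s.per_is.items()):
            rows.append(
                {
                    "replicon_id": s.replicon_id,
                    "kind": s.kind,
                    "is_name": is_name,
                    "complete": v["complete"],
                    "partial": v["partial"],
                    "active": v["active"],
                }
            )
    return pd.DataFrame(
        rows, columns=["replicon_id", "kind", "is_name", "complete", "partial", "active"]
    )


def genome_totals(summaries: list[RepliconSummary]) -> dict[str, int]:
    """Genome-wide complete/partial/active totals across replicons."""
    return {
        "complete": sum(s.complete for s in summaries),
        "partial": sum(s.partial for s in summaries),
        "active": sum(s.active for s in summaries),
    }
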
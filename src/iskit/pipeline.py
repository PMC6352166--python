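"""End-to-end genome scan: search, loci, CRISPR reconciliation, activity, stats."""

from __future__ import annotations

from dataclasses import dataclass, field

from .activity import ActivityCall, assess_locus
from .catalog import ISRecord, Replicon
from .crispr import RepeatArray, cluster_arrays, extract_repeat, find_repeat_copies, reconcile
from .loci import ISLocus, build_loci
from .search import Hit, SearchConfig, search_nt, search_translated
from .summary import RepliconSummary, summarize


@dataclass
class ScanResult:
    hits: list[Hit] = field(default_factory=list)
    loci: list[ISLocus] = field(default_factory=list)
    excluded: list = field(default_factory=list)
    arrays: list[RepeatArray] = field(default_factory=list)
    activity: list[ActivityCall] = field(default_factory=list)
    summaries: list[RepliconSummary] = field(default_factory=list)


def scan_genome(
    replicons: list[Replicon],
    records: list[ISRecord],
    cfg: SearchConfig | None = None,
    crispr_repeat: tuple[str, int, int] | None = None,
    include_translated: bool = True,
) -> ScanResult:
    """Scan replicons for catalog ISs and aggregate the results.

    ``crispr_repeat`` is (source IS name, 1-based start, 1-based end) of
    the repeat unit to screen for tandem arrays; matching partial loci
    inside arrays are excluded from the IS tally before summarizing.
    """
    cfg = cfg or SearchConfig()
    rec_by_name = {r.name: r for r in records}
    result = ScanResult()
    repeat = None
    if crispr_repeat is not None:
        src, lo, hi = crispr_repeat
        repeat = extract_repeat(rec_by_name[src], lo, hi)
    all_loci: list[ISLocus] = []
    for rep in replicons:
        hits: list[Hit] = []
        for rec in records:
            hits.extend(search_nt(rep, rec, cfg))
            if include_translated and rec.transposase_refs:
                hits.extend(search_translated(rep, rec, cfg))
        result.hits.extend(hits)
        loci = build_loci(rep, hits, records)
        if repeat is not None:
            positions = find_repeat_copies(rep, repeat)
            arrays = cluster_arrays(positions, repeat, rep.id)
            result.arrays.extend(arrays)
            loci, excluded = reconcile(loci, arrays)
            result.excluded.extend(excluded)
        for locus in loci:
            if locus.status == "complete" and rec_by_name[locus.is_name].transposase_refs:
                result.activity.append(
                    assess_locus(rep.seq, locus, rec_by_name[locus.is_name], cfg)
                )
        all_loci.extend(loci)
    result.loci = all_loci
    result.summaries = summarize(all_loci, result.activity, replicons)
    return result
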
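"""Tabular and GFF3 output.

Internal coordinates are 0-based half-open throughout the package; all
emitted files are 1-based inclusive (GFF3/BED conventions as each
format requires).
"""

from __future__ import annotations

import pandas as pd

from .crispr import RepeatArray
from .insertions import InsertionCall, PresenceMatrix
from .loci import ISLocus
from .search import Hit

_GFF_HEADER = "##gff-version 3\n"


def hits_frame(hits: list[Hit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "replicon_id": h.replicon_id,
                "start": h.start + 1,
                "end": h.end,
                "strand": h.strand,
                "is_name": h.is_name,
                "level": h.level,
                "identity": round(h.identity, 4),
                "is_cov": round(h.is_cov, 4),
                "score": h.score,
            }
            for h in hits
        ]
    )


def write_hits_gff3(hits: list[Hit], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_GFF_HEADER)
        for h in hits:
            attrs = (
                f"is_name={h.is_name};identity={h.identity:.4f};"
                f"is_cov={h.is_cov:.4f};level={h.level}"
            )
            fh.write(
                f"{h.replicon_id}\tiskit\tdispersed_repeat\t{h.start + 1}\t{h.end}\t"
                f"{h.score}\t{h.strand}\t.\t{attrs}\n"
            )


def loci_frame(loci: list[ISLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "replicon_id": l.replicon_id,
                "start": l.start + 1,
                "end": l.end,
                "strand": l.strand,
                "is_name": l.is_name,
                "status": l.status,
                "coverage": round(l.coverage, 4),
                "tsd": l.tsd_seq or "",
                "ir_evidence": l.ir_evidence,
            }
            for l in loci
        ]
    )


def write_loci_gff3(loci: list[ISLocus], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_GFF_HEADER)
        for l in loci:
            attrs = (
                f"is_name={l.is_name};status={l.status};coverage={l.coverage:.4f};"
                f"tsd={l.tsd_seq or '.'};ir_evidence={l.ir_evidence}"
            )
            fh.write(
                f"{l.replicon_id}\tiskit\tmobile_genetic_element\t{l.start + 1}\t"
                f"{l.end}\t.\t{l.strand}\t.\t{attrs}\n"
            )


def arrays_frame(arrays: list[RepeatArray]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "replicon_id": a.replicon_id,
                "start": a.span[0] + 1,
                "end": a.span[1],
                "strand": a.strand,
                "n_copies": a.n_copies,
                "classification": a.classification,
                "spacers": ",".join(map(str, a.spacer_lengths)),
            }
            for a in arrays
        ]
    )


def write_arrays_gff3(arrays: list[RepeatArray], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_GFF_HEADER)
        for a in arrays:
            for pos in a.copy_positions:
                fh.write(
                    f"{a.replicon_id}\tiskit\tdirect_repeat\t{pos + 1}\t"
                    f"{pos + len(a.repeat_seq)}\t.\t{a.strand}\t.\t"
                    f"classification={a.classification};n_copies={a.n_copies}\n"
                )


def calls_frame(calls: list[InsertionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "replicon_id": c.replicon_id,
                "start": c.start + 1,
                "end": c.end + 1,
                "is_name": c.is_name,
                "left_support": c.left_support,
                "right_support": c.right_support,
                "tsd_len": c.tsd_len,
                "single_flank": int(c.single_flank),
            }
            for c in calls
        ]
    )


def write_calls_bed(calls: list[InsertionCall], path: str) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.replicon_id}\t{c.start}\t{c.end + 1}\t{c.is_name}\t"
                f"{c.left_support + c.right_support}\t+\n"
            )


def write_matrix_tsv(matrix: PresenceMatrix, path: str) -> None:
    out = matrix.table.copy()
    out["start"] = out["start"] + 1
    out["end"] = out["end"] + 1
    out.to_csv(path, sep="\t", index=False)
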
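"""Bundled reference tables from the published *T. thermophilus* IS survey.

Three small tables ship with the package:

* IS typology metadata (family, subgroup, size range, DR length, ORF
  count, catalytic motif class) for the eleven IS types recognized in
  *T. thermophilus* — the default template for synthetic catalogs.
* Per-replicon complete/partial IS copy counts for strains HB27, HB8
  and NAR1.
* Presence/absence of ISTth7 copies at candidate sites on the HB27
  reference chromosome and megaplasmid, across the reference and the
  two laboratory-adapted derivatives HB27A and HB27E.

The count and site tables encode published observations; they are used
as fixtures for the aggregation and comparison stages, not recomputed
by this package.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .catalog import Replicon
from .insertions import InsertionCall
from .loci import ISLocus


def _read(name: str) -> pd.DataFrame:
    with (files("iskit.data") / name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def is_type_metadata() -> pd.DataFrame:
    """IS typology table (one row per IS type recognized in T. thermophilus)."""
    return _read("is_types.tsv")


def tth_is_counts() -> pd.DataFrame:
    """Complete/partial IS copy counts per strain, replicon and IS type."""
    df = _read("tth_is_counts.tsv")
    for col in ("length_bp", "complete", "partial"):
        df[col] = df[col].astype(int)
    return df


def hb27_istth7_sites() -> pd.DataFrame:
    """ISTth7 site presence across the HB27 reference and derived strains."""
    df = _read("hb27_istth7_sites.tsv")
    for col in ("start", "end"):
        df[col] = df[col].astype(int)
    return df


def counts_to_loci(
    counts: pd.DataFrame, strain: str
) -> tuple[list[ISLocus], list[Replicon]]:
    """Expand a count table into placeholder loci for the summary stage.

    Loci get synthetic, non-overlapping coordinates (the aggregation
    only uses replicon, IS type and status); replicons get N-sequences
    of the recorded lengths so occupancy has a denominator but GC is
    undefined.
    """
    sub = counts[counts.strain == strain]
    loci: list[ISLocus] = []
    replicons: list[Replicon] = []
    for (rep_id, kind, length_bp), grp in sub.groupby(
        ["replicon", "kind", "length_bp"], sort=False
    ):
        pos = 1000
        for row in grp.itertuples(index=False):
            for status, n in (("complete", row.complete), ("partial", row.partial)):
                for _ in range(n):
                    size = 1200 if status == "complete" else 400
                    loci.append(
                        ISLocus(
                            is_name=row.is_name,
                            replicon_id=rep_id,
                            start=pos,
                            end=pos + size,
                            strand="+",
                            status=status,
                            coverage=1.0 if status == "complete" else 0.3,
                        )
                    )
                    pos += size + 600
        replicons.append(Replicon(rep_id, kind, "N" * int(length_bp)))
    return loci, replicons


def sites_to_calls(
    sites: pd.DataFrame,
) -> tuple[list[ISLocus], dict[str, list[InsertionCall]]]:
    """Encode the ISTth7 site table as reference loci plus per-sample calls.

    Rows present in the reference become reference loci; rows present
    in a derived sample become insertion calls of that sample, so the
    table can be replayed through :func:`iskit.insertions.compare_samples`.
    """
    sample_cols = [c[3:] for c in sites.columns if c.startswith("in_") and c != "in_reference"]
    ref_loci: list[ISLocus] = []
    calls: dict[str, list[InsertionCall]] = {s: [] for s in sample_cols}
    for row in sites.itertuples(index=False):
        if row.in_reference == "YES":
            ref_loci.append(
                ISLocus(
                    is_name="ISTth7",
                    replicon_id=row.replicon,
                    start=row.start,
                    end=row.end,
                    strand="+",
                    status="complete",
                    coverage=1.0,
                )
            )
        for sample in sample_cols:
            if getattr(row, f"in_{sample}") == "YES":
                calls[sample].append(
                    InsertionCall(
                        replicon_id=row.replicon,
                        start=row.start,
                        end=row.end,
                        is_name="ISTth7",
                        left_support=DEFAULT_FIXTURE_SUPPORT,
                        right_support=DEFAULT_FIXTURE_SUPPORT,
                    )
                )
    return ref_loci, calls


DEFAULT_FIXTURE_SUPPORT = 10
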
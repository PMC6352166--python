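"""Reference catalog of insertion-sequence (IS) types.

An IS catalog pairs one consensus DNA sequence per IS type with the
metadata the rest of the pipeline needs: family/subgroup assignment,
the plausible size range of intact copies, the length of the direct
repeat (target-site duplication) generated on insertion, the number of
transposase ORFs, the catalytic-motif class of the transposase
(DDE or DEDD), and optional terminal inverted-repeat sequences.

On disk a catalog is a nucleotide FASTA of consensus sequences, a
tab-delimited metadata table keyed by IS name, and an optional protein
FASTA of reference transposases (ids ``<is_name>_tnp<k>``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = set("ACGTN")

#: columns of the tab-delimited catalog metadata table, in order.
METADATA_COLUMNS = [
    "name", "family", "subgroup", "min_len", "max_len", "dr_len",
    "orf_count", "motif", "ir_left", "ir_right", "split_orf_tolerant",
]

MIN_CONSENSUS_LEN = 700
MAX_CONSENSUS_LEN = 6000
MAX_DR_LEN = 12


class CatalogError(ValueError):
    """Raised when a catalog file is malformed or violates an invariant."""


@dataclass(frozen=True)
class ProteinRef:
    """A reference transposase protein for one IS type."""

    name: str
    seq: str

    @property
    def aa_len(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ISRecord:
    """One IS catalog entry.

    ``dr_len`` is the characteristic target-site-duplication length in
    bp (0 means the element leaves no duplication).  ``ir_left`` /
    ``ir_right`` are the terminal inverted repeats given 5'->3' on the
    top strand of the consensus; when absent, downstream IR detection
    falls back to the consensus termini.  ``split_orf_tolerant`` marks
    types whose copies may carry the transposase as two consecutive
    ORFs (N- and C-terminal domains) and still be active.
    """

    name: str
    family: str
    subgroup: str | None
    consensus_seq: str
    length_range: tuple[int, int] | None
    dr_len: int
    orf_count: int
    motif_class: str = "unknown"
    ir_left: str | None = None
    ir_right: str | None = None
    transposase_refs: tuple[ProteinRef, ...] = ()
    split_orf_tolerant: bool = False
    #: nucleotide span(s) of the transposase CDS within the consensus,
    #: as (start, end, strand); located lazily, may be empty.
    cds_intervals: tuple[tuple[int, int, str], ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        n = len(self.consensus_seq)
        if not MIN_CONSENSUS_LEN <= n <= MAX_CONSENSUS_LEN:
            raise CatalogError(
                f"{self.name}: consensus length {n} outside "
                f"[{MIN_CONSENSUS_LEN}, {MAX_CONSENSUS_LEN}]"
            )
        if set(self.consensus_seq) - DNA_ALPHABET:
            bad = sorted(set(self.consensus_seq) - DNA_ALPHABET)
            raise CatalogError(f"{self.name}: non-DNA characters {bad} in consensus")
        if self.length_range is not None:
            lo, hi = self.length_range
            if not lo <= n <= hi:
                raise CatalogError(
                    f"{self.name}: consensus length {n} outside declared "
                    f"range [{lo}, {hi}]"
                )
            if lo > hi:
                raise CatalogError(f"{self.name}: empty length range")
        if not 0 <= self.dr_len <= MAX_DR_LEN:
            raise CatalogError(f"{self.name}: dr_len {self.dr_len} outside [0, {MAX_DR_LEN}]")
        if self.orf_count not in (1, 2):
            raise CatalogError(f"{self.name}: orf_count must be 1 or 2")
        if self.motif_class not in ("DDE", "DEDD", "unknown"):
            raise CatalogError(f"{self.name}: unknown motif class {self.motif_class!r}")
        for ir in (self.ir_left, self.ir_right):
            if ir is not None and set(ir) - DNA_ALPHABET:
                raise CatalogError(f"{self.name}: non-DNA characters in IR")

    @property
    def length(self) -> int:
        return len(self.consensus_seq)

    def with_cds_located(self) -> "ISRecord":
        """Return a copy with transposase CDS intervals located in the consensus.

        Each reference protein is searched for verbatim in the six-frame
        translation of the consensus; references that are not encoded
        exactly contribute no interval (downstream coverage then falls
        back to hit spans).
        """
        if not self.transposase_refs:
            return self
        intervals = []
        frames = _six_frame(self.consensus_seq)
        for ref in self.transposase_refs:
            found = None
            for strand, offset, prot in frames:
                idx = prot.find(ref.seq)
                if idx >= 0:
                    nt_len = 3 * (len(ref.seq) + 1)  # CDS including stop codon
                    if strand == "+":
                        start = offset + 3 * idx
                        found = (start, min(start + nt_len, self.length), "+")
                    else:
                        end = self.length - (offset + 3 * idx)
                        found = (max(end - nt_len, 0), end, "-")
                    break
            if found is not None:
                intervals.append(found)
        return replace(self, cds_intervals=tuple(intervals))


@dataclass(frozen=True)
class Replicon:
    """One replicon of a genome (chromosome, megaplasmid or plasmid)."""

    id: str
    kind: str
    seq: str

    def __post_init__(self) -> None:
        if self.kind not in ("chromosome", "megaplasmid", "plasmid"):
            raise ValueError(f"unknown replicon kind {self.kind!r}")
        if set(self.seq) - DNA_ALPHABET:
            raise ValueError(f"{self.id}: non-DNA characters in sequence")

    @property
    def length_bp(self) -> int:
        return len(self.seq)


def _six_frame(seq: str):
    """Yield (strand, frame offset, translated protein) for all six frames."""
    fwd = Seq(seq)
    rev = fwd.reverse_complement()
    for strand, s in (("+", fwd), ("-", rev)):
        for offset in range(3):
            trimmed = s[offset : offset + 3 * ((len(s) - offset) // 3)]
            yield strand, offset, str(trimmed.translate(table=11))


def grade_frequency(n_isolates: int) -> str:
    """Grade how widespread an IS type is across isolates of a genus.

    ``+++`` (high) for presence in more than 6 isolates, ``++``
    (moderate) for 3-6 isolates, ``+`` (low) for 2 or fewer.
    """
    if n_isolates < 0:
        raise ValueError("n_isolates must be non-negative")
    if n_isolates > 6:
        return "+++"
    if n_isolates >= 3:
        return "++"
    return "+"


def _parse_optional(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    if text in ("", "-", ".", "NA", "nan"):
        return None
    return text


def load_catalog(
    fasta_path: str | Path,
    metadata_path: str | Path,
    proteins_path: str | Path | None = None,
) -> list[ISRecord]:
    """Load and validate an IS catalog.

    FASTA ids and metadata ``name`` values must match one to one.
    Records violating an invariant are rejected with their metadata row
    number.  Transposase references, when a protein FASTA is given, are
    attached by the ``<is_name>_tnp<k>`` id convention.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise CatalogError(f"duplicate consensus id {rec.id!r} in FASTA")
        seqs[rec.id] = str(rec.seq).upper()

    proteins: dict[str, list[ProteinRef]] = {}
    if proteins_path is not None:
        for rec in SeqIO.parse(str(proteins_path), "fasta"):
            base = rec.id.rsplit("_tnp", 1)[0]
            proteins.setdefault(base, []).append(ProteinRef(rec.id, str(rec.seq).upper()))

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
    missing_cols = [c for c in METADATA_COLUMNS[:8] if c not in meta.columns]
    if missing_cols:
        raise CatalogError(f"metadata missing columns {missing_cols}")

    records: list[ISRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(meta.itertuples(index=False), start=2):  # 1-based + header
        name = row.name.strip()
        if name in seen:
            raise CatalogError(f"metadata row {i}: duplicate name {name!r}")
        seen.add(name)
        if name not in seqs:
            raise CatalogError(f"metadata row {i}: no consensus sequence for {name!r}")
        lo, hi = _parse_optional(row.min_len), _parse_optional(row.max_len)
        length_range = (int(lo), int(hi)) if lo is not None and hi is not None else None
        try:
            rec = ISRecord(
                name=name,
                family=row.family.strip(),
                subgroup=_parse_optional(row.subgroup),
                consensus_seq=seqs[name],
                length_range=length_range,
                dr_len=int(row.dr_len),
                orf_count=int(row.orf_count),
                motif_class=_parse_optional(row.motif) or "unknown",
                ir_left=_parse_optional(getattr(row, "ir_left", None)),
                ir_right=_parse_optional(getattr(row, "ir_right", None)),
                transposase_refs=tuple(proteins.get(name, ())),
                split_orf_tolerant=_parse_optional(getattr(row, "split_orf_tolerant", None))
                in ("1", "true", "True"),
            )
        except (CatalogError, ValueError) as exc:
            raise CatalogError(f"metadata row {i}: {exc}") from exc
        records.append(rec.with_cds_located())

    orphans = set(seqs) - seen
    if orphans:
        raise CatalogError(f"consensus sequences without metadata rows: {sorted(orphans)}")
    return records


def write_catalog(
    records: list[ISRecord],
    fasta_path: str | Path,
    metadata_path: str | Path,
    proteins_path: str | Path | None = None,
) -> None:
    """Write a catalog back to FASTA + TSV (+ optional protein FASTA)."""
    SeqIO.write(
        [SeqRecord(Seq(r.consensus_seq), id=r.name, description="") for r in records],
        str(fasta_path),
        "fasta",
    )
    rows = []
    for r in records:
        rows.append(
            {
                "name": r.name,
                "family": r.family,
                "subgroup": r.subgroup or "",
                "min_len": r.length_range[0] if r.length_range else "",
                "max_len": r.length_range[1] if r.length_range else "",
                "dr_len": r.dr_len,
                "orf_count": r.orf_count,
                "motif": r.motif_class,
                "ir_left": r.ir_left or "",
                "ir_right": r.ir_right or "",
                "split_orf_tolerant": int(r.split_orf_tolerant),
            }
        )
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(metadata_path, sep="\t", index=False)
    if proteins_path is not None:
        prots = [
            SeqRecord(Seq(p.seq), id=p.name, description="")
            for r in records
            for p in r.transposase_refs
        ]
        SeqIO.write(prots, str(proteins_path), "fasta")


def load_replicons(fasta_path: str | Path, kinds: dict[str, str] | None = None) -> list[Replicon]:
    """Read replicons from FASTA; ``kinds`` maps id -> replicon kind.

    Unlisted replicons default to ``chromosome`` for the first sequence
    and ``plasmid`` otherwise.
    """
    out = []
    for i, rec in enumerate(SeqIO.parse(str(fasta_path), "fasta")):
        kind = (kinds or {}).get(rec.id, "chromosome" if i == 0 else "plasmid")
        out.append(Replicon(rec.id, kind, str(rec.seq).upper()))
    return out
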
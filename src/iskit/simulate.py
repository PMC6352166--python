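"""Ground-truthed synthetic genomes, catalogs, strains and read alignments.

Everything the analysis consumes can be generated here with known
truth: multi-replicon genomes at a *Thermus*-like GC content (68.1%),
planted complete IS copies with intact inverted repeats and target-site
duplications, truncated IS scars, tandem repeat arrays with 30-40 bp
spacers mimicking the IS-derived CRISPR arrays, laboratory-derived
strains carrying extra insertions, and coordinate-sorted SAM alignments
of the derived strains against the parent.

Alignment records are synthesized directly from the known junction
coordinates instead of running a read mapper, so clip positions are
exact and no external aligner is needed; mapper-induced artifacts
(ambiguous placement, indel realignment) are therefore absent from
simulated data.  Reads carry i.i.d. substitution errors only.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

import numpy as np
import pysam

from .align import revcomp
from .catalog import ISRecord, ProteinRef, Replicon
from .crispr import extract_repeat

AA20 = "ACDEFGHIKLMNPQRSTVWY"
# one fixed codon per amino acid (valid under translation table 11)
_CODON = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGC",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}

DEFAULT_GC = 0.681
DEFAULT_MIN_SEPARATION = 500
IR_LEN = 16


def random_dna(rng: np.random.Generator, n: int, gc: float = DEFAULT_GC) -> str:
    """i.i.d. random DNA at the given GC fraction."""
    p_gc, p_at = gc / 2, (1 - gc) / 2
    codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    draw = rng.choice(4, size=n, p=[p_at, p_gc, p_gc, p_at])
    return codes[draw].tobytes().decode("ascii")


def _random_protein(rng: np.random.Generator, n: int, motif_class: str) -> str:
    aa = list(rng.choice(list(AA20), size=n))
    aa[0] = "M"
    if motif_class in ("DDE", "DEDD"):
        pattern = motif_class
        gaps = rng.integers(60, 130, size=len(pattern) - 1)
        start = int(n * 0.25)
        positions = [start]
        for g in gaps:
            positions.append(positions[-1] + int(g))
        if positions[-1] >= n - 2:
            scale = (n - 3 - start) / (positions[-1] - start)
            positions = [start] + [start + max(41, int((p - start) * scale)) for p in positions[1:]]
        for pos, res in zip(positions, pattern):
            aa[pos] = res
    return "".join(aa)


def _encode_protein_cds(protein: str) -> str:
    return "".join(_CODON[a] for a in protein) + "TAA"


def synth_is_record(
    rng: np.random.Generator,
    name: str,
    family: str = "IS5",
    subgroup: str | None = None,
    length_range: tuple[int, int] = (900, 1150),
    dr_len: int = 8,
    orf_count: int = 1,
    motif_class: str = "DDE",
    split_orf_tolerant: bool = False,
    gc: float = DEFAULT_GC,
) -> ISRecord:
    """Build one synthetic IS type: IRs, transposase ORF(s), filler.

    The consensus is ``ir_left + 5'UTR + CDS(s) + filler + ir_right``
    with the target length set to the middle of the catalog size range;
    the reference transposases are exactly the encoded proteins, so the
    CDS can always be located in the consensus.
    """
    lo, hi = length_range
    total = (lo + hi) // 2
    utr = 10
    budget = total - 2 * IR_LEN - utr * (orf_count + 1)
    aa_per_orf = (budget // orf_count - 3) // 3 - 1
    if aa_per_orf < 90:
        raise ValueError(f"{name}: size range too small for a transposase ORF")
    ir_left = random_dna(rng, IR_LEN, gc)
    parts = [ir_left]
    proteins: list[ProteinRef] = []
    for k in range(orf_count):
        parts.append(random_dna(rng, utr, gc))
        protein = _random_protein(rng, aa_per_orf, motif_class if k == orf_count - 1 else "none")
        proteins.append(ProteinRef(f"{name}_tnp{k + 1}", protein))
        parts.append(_encode_protein_cds(protein))
    used = sum(len(p) for p in parts) + IR_LEN
    parts.append(random_dna(rng, total - used, gc))
    parts.append(revcomp(ir_left))
    consensus = "".join(parts)
    rec = ISRecord(
        name=name,
        family=family,
        subgroup=subgroup,
        consensus_seq=consensus,
        length_range=length_range,
        dr_len=dr_len,
        orf_count=orf_count,
        motif_class=motif_class,
        ir_left=ir_left,
        ir_right=revcomp(ir_left),
        transposase_refs=tuple(proteins),
        split_orf_tolerant=split_orf_tolerant,
    )
    return rec.with_cds_located()


def make_catalog(
    rng: np.random.Generator, metadata=None, names: list[str] | None = None
) -> list[ISRecord]:
    """Synthetic catalog driven by an IS-type metadata table.

    ``metadata`` defaults to the bundled *T. thermophilus* IS typology
    table; ``names`` restricts which types are built.
    """
    from .datasets import is_type_metadata

    meta = metadata if metadata is not None else is_type_metadata()
    records = []
    for row in meta.itertuples(index=False):
        if names is not None and row.name not in names:
            continue
        records.append(
            synth_is_record(
                rng,
                name=row.name,
                family=row.family,
                subgroup=row.subgroup or None,
                length_range=(int(row.min_len), int(row.max_len)),
                dr_len=int(row.dr_len),
                orf_count=int(row.orf_count),
                motif_class=row.motif,
                split_orf_tolerant=bool(int(row.split_orf_tolerant)),
            )
        )
    return records


@dataclass(frozen=True)
class RepliconSpec:
    id: str
    kind: str
    length_bp: int


@dataclass(frozen=True)
class ISPlant:
    """Planting plan for one IS type on one replicon."""

    replicon_id: str
    is_name: str
    n_complete: int = 0
    n_partial: int = 0
    truncation: float = 0.4


@dataclass(frozen=True)
class CrisprSpec:
    """Plan for one tandem repeat array derived from an IS segment."""

    replicon_id: str
    source_is: str
    n_copies: int = 5
    repeat_start: int = 1165  # 1-based inclusive, within the source consensus
    repeat_end: int = 1196
    spacer_min: int = 30
    spacer_max: int = 40


@dataclass(frozen=True)
class ReadPlan:
    read_len: int = 150
    coverage: float = 30.0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.read_len < 50:
            raise ValueError("read_len must be >= 50")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


@dataclass(frozen=True)
class SimConfig:
    seed: int
    replicons: tuple[RepliconSpec, ...]
    gc: float = DEFAULT_GC
    is_plans: tuple[ISPlant, ...] = ()
    crispr: CrisprSpec | None = None
    min_separation: int = DEFAULT_MIN_SEPARATION
    read_plan: ReadPlan = field(default_factory=ReadPlan)


@dataclass(frozen=True)
class PlantedLocus:
    replicon_id: str
    is_name: str
    start: int
    end: int
    strand: str
    status: str  # complete | partial
    tsd: str | None
    fraction: float  # fraction of the consensus planted


@dataclass(frozen=True)
class PlantedArray:
    replicon_id: str
    repeat_seq: str
    positions: tuple[int, ...]
    strand: str


@dataclass(frozen=True)
class NovelInsertion:
    replicon_id: str
    site: int  # parent coordinate of the insertion point
    is_name: str
    tsd_len: int
    strand: str


@dataclass
class GroundTruth:
    loci: list[PlantedLocus] = field(default_factory=list)
    arrays: list[PlantedArray] = field(default_factory=list)
    novel: dict[str, list[NovelInsertion]] = field(default_factory=dict)


def make_genome(
    cfg: SimConfig, records: list[ISRecord]
) -> tuple[list[Replicon], GroundTruth]:
    """Assemble replicons with planted elements and exact ground truth.

    Background bases are i.i.d. at ``cfg.gc``.  Complete copies carry a
    freshly drawn target-site duplication of the catalog DR length on
    both flanks and intact termini; partial copies are contiguous
    consensus fragments (5' or 3' half chosen at random); the repeat
    array tiles a slice of the designated source IS.  Planted elements
    are separated by at least ``cfg.min_separation`` bp of background.
    Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    rec_by_name = {r.name: r for r in records}
    truth = GroundTruth()
    replicons: list[Replicon] = []
    for spec in cfg.replicons:
        chunks: list[tuple[str, dict | None]] = []
        for plan in cfg.is_plans:
            if plan.replicon_id != spec.id:
                continue
            rec = rec_by_name[plan.is_name]
            for _ in range(plan.n_complete):
                strand = "+" if rng.random() < 0.5 else "-"
                t = rec.dr_len
                tsd = random_dna(rng, t, cfg.gc) if t else ""
                core = rec.consensus_seq if strand == "+" else revcomp(rec.consensus_seq)
                chunks.append(
                    (
                        tsd + core + tsd,
                        {
                            "is_name": rec.name,
                            "offset": t,
                            "length": len(core),
                            "strand": strand,
                            "status": "complete",
                            "tsd": tsd or None,
                            "fraction": 1.0,
                        },
                    )
                )
            for _ in range(plan.n_partial):
                strand = "+" if rng.random() < 0.5 else "-"
                keep = max(60, int(round(plan.truncation * rec.length)))
                frag = (
                    rec.consensus_seq[:keep]
                    if rng.random() < 0.5
                    else rec.consensus_seq[-keep:]
                )
                if strand == "-":
                    frag = revcomp(frag)
                chunks.append(
                    (
                        frag,
                        {
                            "is_name": rec.name,
                            "offset": 0,
                            "length": keep,
                            "strand": strand,
                            "status": "partial",
                            "tsd": None,
                            "fraction": keep / rec.length,
                        },
                    )
                )
        array_chunk = None
        if cfg.crispr is not None and cfg.crispr.replicon_id == spec.id:
            src = rec_by_name[cfg.crispr.source_is]
            repeat = extract_repeat(src, cfg.crispr.repeat_start, cfg.crispr.repeat_end)
            parts, rel_positions, pos = [], [], 0
            for i in range(cfg.crispr.n_copies):
                rel_positions.append(pos)
                parts.append(repeat)
                pos += len(repeat)
                if i < cfg.crispr.n_copies - 1:
                    gap = int(rng.integers(cfg.crispr.spacer_min, cfg.crispr.spacer_max + 1))
                    parts.append(random_dna(rng, gap, cfg.gc))
                    pos += gap
            array_chunk = ("".join(parts), {"array": True, "repeat": repeat, "rel": rel_positions})
            chunks.append(array_chunk)

        order = rng.permutation(len(chunks)) if chunks else []
        chunks = [chunks[i] for i in order]
        total_planted = sum(len(c) for c, _ in chunks)
        n_gaps = len(chunks) + 1
        background = spec.length_bp - total_planted
        if background < n_gaps * cfg.min_separation:
            raise ValueError(
                f"{spec.id}: plan does not fit with {cfg.min_separation} bp separation"
            )
        extra = background - n_gaps * cfg.min_separation
        gap_extra = rng.multinomial(extra, [1 / n_gaps] * n_gaps)
        parts = []
        pos = 0
        for (chunk, meta), g in zip(chunks, gap_extra[:-1]):
            gap_len = cfg.min_separation + int(g)
            parts.append(random_dna(rng, gap_len, cfg.gc))
            pos += gap_len
            parts.append(chunk)
            if meta is not None and "array" in meta:
                truth.arrays.append(
                    PlantedArray(
                        spec.id,
                        meta["repeat"],
                        tuple(pos + r for r in meta["rel"]),
                        "+",
                    )
                )
            elif meta is not None:
                truth.loci.append(
                    PlantedLocus(
                        spec.id,
                        meta["is_name"],
                        pos + meta["offset"],
                        pos + meta["offset"] + meta["length"],
                        meta["strand"],
                        meta["status"],
                        meta["tsd"],
                        meta["fraction"],
                    )
                )
            pos += len(chunk)
        parts.append(random_dna(rng, cfg.min_separation + int(gap_extra[-1]), cfg.gc))
        seq = "".join(parts)
        assert len(seq) == spec.length_bp
        replicons.append(Replicon(spec.id, spec.kind, seq))
    return replicons, truth


def derive_strain(
    parent_replicons: list[Replicon],
    insertions: list[tuple[str, int, str]],
    records: list[ISRecord],
    rng: np.random.Generator | None = None,
    existing_loci: list[PlantedLocus] | None = None,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> tuple[list[Replicon], list[NovelInsertion]]:
    """Insert extra IS copies into a parent genome.

    ``insertions`` is a list of (replicon_id, site, is_name); each site
    receives the full consensus plus a target-site duplication of the
    catalog DR length.  Sites must be >= min_separation apart and not
    fall inside existing planted loci.
    """
    rec_by_name = {r.name: r for r in records}
    by_rep: dict[str, list[tuple[int, str]]] = {}
    for rep_id, site, is_name in insertions:
        by_rep.setdefault(rep_id, []).append((site, is_name))
    for rep_id, sites in by_rep.items():
        sites.sort()
        for (a, _), (b, _) in zip(sites, sites[1:]):
            if b - a < min_separation:
                raise ValueError(f"{rep_id}: insertion sites closer than {min_separation} bp")
        for site, _ in sites:
            for locus in existing_loci or []:
                if locus.replicon_id == rep_id and locus.start <= site < locus.end:
                    raise ValueError(f"{rep_id}:{site} falls inside an existing locus")
    derived: list[Replicon] = []
    novel: list[NovelInsertion] = []
    for rep in parent_replicons:
        sites = by_rep.get(rep.id, [])
        parts, prev = [], 0
        for site, is_name in sites:
            rec = rec_by_name[is_name]
            t = rec.dr_len
            parts.append(rep.seq[prev : site + t])
            parts.append(rec.consensus_seq)
            prev = site
            novel.append(NovelInsertion(rep.id, site, is_name, t, "+"))
        parts.append(rep.seq[prev:])
        derived.append(Replicon(rep.id, rep.kind, "".join(parts)))
    return derived, novel


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def simulate_alignments(
    derived_replicons: list[Replicon],
    parent_replicons: list[Replicon],
    insertions: list[NovelInsertion],
    records: list[ISRecord],
    read_plan: ReadPlan,
    seed: int,
    out_path: str,
) -> int:
    """Emit coordinate-sorted SAM of derived-strain reads vs the parent.

    Read starts are uniform over each derived replicon.  Reads fully
    inside sequence shared with the parent get full-match CIGARs at
    parent coordinates; reads straddling a novel junction are
    soft-clipped at the junction with the clip taken from the inserted
    element; reads fully inside an inserted element are emitted
    unmapped.  Substitution errors are i.i.d. at the configured rate.
    Returns the number of records written.
    """
    rng = np.random.default_rng(seed)
    rec_by_name = {r.name: r for r in records}
    parent_by_id = {r.id: r for r in parent_replicons}
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": r.id, "LN": r.length_bp} for r in parent_replicons],
        }
    )
    tid = {r.id: i for i, r in enumerate(parent_replicons)}
    mapped: list[tuple[int, int, str, str, str]] = []  # (tid, pos, cigar, seq, name)
    unmapped: list[tuple[str, str]] = []
    rl = read_plan.read_len
    for rep in derived_replicons:
        ins = sorted(
            (n for n in insertions if n.replicon_id == rep.id), key=lambda n: n.site
        )
        # derived-coordinate block table for the inserted elements
        blocks, offs = [], [0]
        off = 0
        for n in ins:
            L = rec_by_name[n.is_name].length
            b = n.site + n.tsd_len + off
            blocks.append((b, b + L, n.site))
            off += n.tsd_len + L
            offs.append(off)
        expected_len = parent_by_id[rep.id].length_bp + off
        if rep.length_bp != expected_len:
            raise ValueError(f"{rep.id}: derived length inconsistent with insertions")
        n_reads = int(round(read_plan.coverage * rep.length_bp / rl))
        starts = np.sort(rng.integers(0, rep.length_bp - rl + 1, size=n_reads))
        b_starts = [b for b, _, _ in blocks]
        for idx, s in enumerate(starts):
            s = int(s)
            seq = _apply_errors(rng, rep.seq[s : s + rl], read_plan.error_rate)
            name = f"{rep.id}_r{idx}"
            k = bisect.bisect_right(b_starts, s) - 1
            if k >= 0 and s < blocks[k][1]:  # starts inside block k
                if s + rl <= blocks[k][1]:
                    unmapped.append((name, seq))
                else:  # exits through the right junction
                    m = s + rl - blocks[k][1]
                    mapped.append(
                        (tid[rep.id], blocks[k][2], f"{rl - m}S{m}M", seq, name)
                    )
                continue
            nxt = k + 1
            if nxt < len(blocks) and s + rl > blocks[nxt][0]:  # crosses left junction
                m = blocks[nxt][0] - s
                # reads are shorter than any element, so they never span one
                mapped.append((tid[rep.id], s - offs[nxt], f"{m}M{rl - m}S", seq, name))
                continue
            mapped.append((tid[rep.id], s - offs[k + 1], f"{rl}M", seq, name))
    mapped.sort(key=lambda t: (t[0], t[1], t[4]))
    with pysam.AlignmentFile(out_path, "w", header=header) as fh:
        for t, pos, cigar, seq, name in mapped:
            a = pysam.AlignedSegment(header)
            a.query_name = name
            a.query_sequence = seq
            a.flag = 0
            a.reference_id = t
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = cigar
            fh.write(a)
        for name, seq in unmapped:
            a = pysam.AlignedSegment(header)
            a.query_name = name
            a.query_sequence = seq
            a.flag = 4
            a.reference_id = -1
            a.reference_start = -1
            a.mapping_quality = 0
            fh.write(a)
    return len(mapped) + len(unmapped)
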
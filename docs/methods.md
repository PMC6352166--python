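# Methods

## Similarity search

Both search stages are self-contained seed-and-extend local aligners;
no external search engine is wrapped.

**Model.** Local alignment is Smith–Waterman with affine gaps: a gap's
first base costs `gap_open`, each further base `gap_extend`. Identity
is defined as matches / aligned columns, with gap columns counted as
non-matches; `N` (and protein `X`) never match anything, including
themselves, so assembly gaps cannot inflate identity. Multiple
alignments per query/subject pair are enumerated best-score first with
subject masking (Waterman–Eggert style): after each traceback the
alignment's subject interval becomes a hard barrier and only the
affected dynamic-programming columns are recomputed, so reported
alignments are always subject-disjoint. Ties at equal score resolve to
the first maximal cell in row-major order (smallest query end, then
smallest subject end), making results deterministic.

**Thresholds.** The nucleotide stage reports alignments at identity
≥ 0.80 spanning ≥ 50 columns (`min_hit_len`); the translated stage
(six-frame translation of the replicon, table 11, against reference
transposase proteins) reports ≥ 0.30 identity over ≥ 50 amino acids.
The identity cutoffs are the standard operating points for IS
annotation in *Thermus*; the length floors are this package's choice —
E-values are deliberately not computed, so a length floor is what
separates signal from the dense background of micro-alignments. At 80%
identity a 25 bp floor already admits chance hits in 68%-GC background
(observed a handful per 150 kb), which is why 50 bp is the default.

**Scoring.** Nucleotide scores are +2/−3 with gaps −5/−2. Protein
scores are milder, +2/−1 with gaps −4/−1: with harsh mismatch
penalties a full-length transposase homolog at ~1/3 identity is not a
positive-scoring local alignment at all, whereas the milder scheme
keeps per-column drift positive down to roughly the reporting
threshold. This stands in for a substitution matrix; it recovers
full-length distant homologies but, unlike BLOSUM-scored search, gives
no credit for conservative substitutions, so borderline (25–30%
identity) homologs are detected less reliably.

**Seeding and its blind spot.** Exact k-mer seeds (k = 12 nt / 5 aa by
default) are grouped per diagonal, extended ungapped with an x-drop,
and extensions above a filter score open a padded window that is then
mined with the full DP. Subjects up to 2 kb are mined whole once any
seed fires, which makes the seeded search exactly equivalent to the
exhaustive oracle (`sw_oracle`) at that scale; larger subjects use the
windowed heuristic. Seeding has a provable blind spot: an alignment of
c columns with e non-match columns need only contain an exact run of
⌈(c−e)/(e+1)⌉ matches, which at 82% identity tends to ~4.6 — below any
usable seed length. Short near-threshold alignments can therefore be
missed regardless of tuning; alignments of ≥ 45 columns at ≥ 2 identity
points above threshold are recovered reliably in randomized testing
(200+ instances per run). All planted and biological hits are far
longer than that.

**Identity filtering is per maximal alignment.** The enumeration mines
alignments in score order and applies the identity/length filters to
each mined alignment; sub-segments of a failed alignment are not
re-mined. A copy diverged to 79% identity therefore produces no hit:
its maximal-score alignment spans the whole copy at ~0.79 and is
rejected whole, rather than being fragmented into shorter
higher-identity pieces.

## Locus building

Hits of the same IS type and strand within 100 bp chain into one
locus; nucleotide and translated hits co-support a locus, with
translated hits projected onto consensus coordinates through the
located transposase CDS. Locus coverage is the union of consensus
intervals covered. A locus is **complete** when coverage ≥ 0.95
(inclusive) and its genomic length lies in [0.9·min, 1.1·max] of the
catalog size range; the field's complete/partial dichotomy has no
agreed numerical definition, so both knobs are exposed
(`complete_cov_min`, the size window). Locus boundaries come from the
outermost supporting hit ends, not from IR extension — deterministic
and oracle-checkable, at the cost of a few base pairs of slack at scar
edges where chance flank matches extend an alignment.

**TSD.** The duplication is called only when the `dr_len`-bp windows
immediately flanking the locus are identical (and N-free); loci
within `dr_len` of a replicon edge return no call and are flagged.

**IR.** The locus sequence is oriented to the IS frame and its termini
compared against the catalog IRs (or the consensus termini, 25 bp,
when the catalog has none) at ≤ 3 mismatches per side.

## Activity assessment

Only complete loci are assessed. ORFs (≥ 80 aa, starts ATG/GTG/TTG,
table 11, one ORF per stop-to-stop segment opened at the first start)
are aligned to each reference transposase; coverage is measured on the
reference so insertions in the copy cannot inflate it. A copy is
**active** when every reference protein is covered ≥ 90% by a single
ORF, or — for types flagged split-ORF-tolerant — by two consecutive
ORFs in the *same reading frame* matching the N- and C-terminal
regions in genomic order with ≤ 30 aa reference overlap. The
same-frame requirement is deliberate: a 1 bp deletion in an intact
copy produces exactly an N+C pair in *different* frames, and the
package's position is that such a copy is frameshifted, not active.
Inactive copies carry a reason: `truncated` (insufficient coverage),
`frameshift` (joint coverage across frames), `interrupted` (joint
coverage within one frame but split), and the motif annotation adds a
`motif_absent_note` when the expected DDE/DEDD pattern (inter-residue
gaps 40–160 aa) is not found. Motif content never flips a verdict —
motifs group IS families; they do not distinguish live copies.

## CRISPR-repeat reconciliation

The repeat unit (by default the 32 bp slice at consensus positions
1165–1196 of the IS1000-type element) is scanned exactly (0
mismatches, per the observed identity of the recruited repeats;
tolerance configurable) on both strands. Consecutive same-strand
copies whose gap lies in [30, 40] bp chain into an array; arrays with
≥ 3 copies are classified as CRISPR arrays, smaller chains as isolated
fragments. Partial IS loci lying within an array span (± 20 bp of
alignment jitter) are excluded from the IS tally and logged; complete
loci are never removed, and isolated copies remain genuine IS
fragments. Three copies is the minimal configuration that
distinguishes an array from a chance doubled fragment; spacer
sequences themselves are not extracted or analyzed.

## Insertion calling from soft clips

Primary alignments with MAPQ ≥ 20 contribute soft-clipped read ends of
≥ 10 bp; reads identical in (position, CIGAR, sequence) count once so
PCR duplicates cannot inflate support. Clips cluster per (replicon,
side) within a 10 bp window; each cluster's junction-anchored majority
consensus is compared gaplessly against the first/last 60 bp of each
catalog consensus and their reverse complements at ≥ 0.90 identity. A
left-side cluster at position p and a right-side cluster at p + t − 1
of the same IS pair into one call with TSD length t (offsets from −1,
i.e. no duplication, up to 20 bp are accepted); each flank needs ≥ 4
supporting reads, or a lone flank ≥ 8 reads (flagged single-flank).
The support defaults are conventional for clip-based callers and are
exposed in the API. Cross-sample comparison merges reference loci and
per-sample calls whose starts lie within 10 bp into one row of a
presence/absence matrix; novel counts are rows absent from the
reference, shared-novel counts their pairwise intersections.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
i.i.d. background at GC 0.681 (the *T. thermophilus* host genome
mean), planted complete copies with freshly drawn TSDs of the catalog
DR length and intact termini, partial copies as contiguous 5′ or 3′
consensus fragments (default 40% of the element), repeat arrays tiling
the 32 bp slice with uniform 30–40 bp spacers, ≥ 500 bp of background
between planted elements, and derived strains carrying extra
insertions. Synthetic IS types are built from the bundled typology
table: 16 bp IRs (right = reverse complement of left), one or two
CDSs encoding random proteins with the family's DDE/DEDD motif planted
at valid spacings, deterministic codon encoding so the transposase CDS
is always locatable in the consensus.

Read alignments are synthesized directly from the known junction
coordinates rather than by running a mapper: read starts are uniform
over the derived genome, reads inside shared sequence emit full-match
CIGARs at parent coordinates, junction-straddling reads emit
soft-clipped CIGARs with the clip taken from the inserted element, and
reads fully inside an insertion are emitted unmapped. Errors are
i.i.d. substitutions only. Everything is reproducible from one seed.

What this does *not* emulate — and hence what passing tests do not
show about real data: repeat structure and compositional heterogeneity
of real backgrounds, mapper artifacts (ambiguous placement, clip-end
realignment, indel noise), sequencing indels, coverage bias, and IS
copies diverged from their consensus. The recovery properties measured
here are therefore upper bounds on real-data performance.

## Problem sizes and determinism

The test suite and the acceptance script run planted-recovery scans on
two-replicon genomes of 100 kb + 50 kb with 10 complete + 5 partial
copies from three IS types and one 5-copy array (20 seeds in the
suite), and insertion-calling simulations on 60 kb genomes at 30×
coverage with 3–4 insertions per strain — sizes chosen so the whole
validation cycle completes in minutes on one CPU while every planted
element count remains exactly checkable. All randomness flows through
explicit `numpy` generators seeded from a single integer; identical
inputs and configuration produce byte-identical outputs, including
simulated SAM files.

## Known limitations

- Identity-scored protein search under-detects borderline homologs
  compared to matrix-scored BLASTX; no profile/HMM search.
- No E-value statistics; length/identity floors take their place.
- Nested or composite elements of the *same* IS type merge into one
  locus; different types may overlap freely.
- The caller uses soft-clip evidence only (no discordant read pairs)
  and reports flank-pair spans, not element orientation.
- Genome-scale windowed search is heuristic beyond 2 kb subjects; the
  exact-equivalence guarantee applies to the oracle-tested domain.
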
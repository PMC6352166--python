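"""Independent brute-force oracles used only by the test suite.

Each oracle is a deliberately naive re-implementation of the quantity
it checks, sharing no code with the package internals.
"""

from __future__ import annotations

NEG = -(10**9)


def naive_local_score(q: str, s: str, match: int, mismatch: int, go: int, ge: int) -> int:
    """Best local alignment score by plain-Python affine-gap DP.

    Same model as the package: a gap's first base costs ``go``, each
    further base ``ge``; N/X/* never match.
    """
    n, m = len(q), len(s)
    best = 0
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            a, b = q[i - 1], s[j - 1]
            sub = match if (a == b and a not in "NX*") else mismatch
            E[i][j] = max(H[i][j - 1] + go, E[i][j - 1] + ge)
            F[i][j] = max(H[i - 1][j] + go, F[i - 1][j] + ge)
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def naive_orf_scan(seq: str, min_aa: int) -> set[tuple[int, int, str]]:
    """(start, end, strand) of all ORFs by direct codon walking.

    One ORF per stop-to-stop stretch, opened at the first start codon;
    coordinates on the forward strand, stop codon included.
    """
    starts = {"ATG", "GTG", "TTG"}
    stops = {"TAA", "TAG", "TGA"}
    comp = str.maketrans("ACGTN", "TGCAN")
    out: set[tuple[int, int, str]] = set()
    for strand in ("+", "-"):
        s = seq if strand == "+" else seq.translate(comp)[::-1]
        n = len(s)
        for frame in range(3):
            open_at = None
            for pos in range(frame, n - 2, 3):
                codon = s[pos : pos + 3]
                if codon in stops:
                    if open_at is not None and (pos + 3 - open_at) // 3 - 1 >= min_aa:
                        if strand == "+":
                            out.add((open_at, pos + 3, "+"))
                        else:
                            out.add((n - (pos + 3), n - open_at, "-"))
                    open_at = None
                elif open_at is None and codon in starts:
                    open_at = pos
    return out


def naive_repeat_scan(seq: str, probe: str, max_mismatch: int) -> list[int]:
    """Sliding-window Hamming scan; N never matches."""
    k = len(probe)
    hits = []
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        mism = sum(
            1 for a, b in zip(window, probe) if a != b or a == "N" or b == "N"
        )
        if mism <= max_mismatch:
            hits.append(i)
    return hits


def interval_union_len(intervals: list[tuple[int, int]], size: int) -> int:
    """Union length by explicit bitmap."""
    mask = bytearray(size)
    for lo, hi in intervals:
        for i in range(lo, hi):
            mask[i] = 1
    return sum(mask)
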
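"""Independent reference implementations used only to check the package:
deliberately naive, position-by-position / enumeration-style code with no
shared logic with the implementations under test."""

from __future__ import annotations

import itertools

_STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTN", "TGCAN")


def _rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# ORF enumeration: test every position independently
# ---------------------------------------------------------------------------

def _codon_at(seq: str, pos: int, circular: bool) -> str | None:
    n = len(seq)
    if circular:
        return "".join(seq[(pos + k) % n] for k in range(3))
    if pos + 3 > n:
        return None
    return seq[pos : pos + 3]


def _walk_to_stop(seq: str, t0: int, circular: bool) -> int | None:
    """nt length of the ORF starting at t0 (ATG assumed), or None if no
    in-frame stop within one genome length."""
    n = len(seq)
    for k in range(1, n // 3 + 1):
        codon = _codon_at(seq, t0 + 3 * (k - 1), circular)
        if codon is None:
            return None
        if codon in _STOPS:
            return 3 * k
    return None


def _is_maximal(seq: str, t0: int, circular: bool) -> bool:
    """No ATG strictly upstream in the same frame before the previous
    in-frame stop."""
    n = len(seq)
    for k in range(1, n // 3 + 1):
        pos = t0 - 3 * k
        if not circular and pos < 0:
            return True
        codon = _codon_at(seq, pos % n if circular else pos, circular)
        if codon is None or codon in _STOPS:
            return True
        if codon == "ATG":
            # an upstream same-frame ATG reaching the same stop exists
            return False
    return True


def brute_force_orfs(sequence: str, circular: bool, min_nt: int):
    """All maximal ORFs on both strands as (start_1based, strand,
    length_nt) in genome coordinates."""
    out = set()
    n = len(sequence)
    for strand, seq in ((1, sequence), (-1, _rc(sequence))):
        for t0 in range(n):
            if _codon_at(seq, t0, circular) != "ATG":
                continue
            length = _walk_to_stop(seq, t0, circular)
            if length is None or length < min_nt:
                continue
            if not _is_maximal(seq, t0, circular):
                continue
            start = t0 + 1 if strand == 1 else n - t0
            out.add((start, strand, length))
    return out


# ---------------------------------------------------------------------------
# Per-base interval overlap
# ---------------------------------------------------------------------------

def covered_positions(feature, genome_length: int) -> set[int]:
    pos = set()
    p = feature.start
    step = feature.strand
    for _ in range(feature.length_nt):
        pos.add(p)
        p = (p - 1 + step) % genome_length + 1
    return pos


def per_base_overlap(f1, f2, genome_length: int) -> int:
    return len(covered_positions(f1, genome_length) & covered_positions(f2, genome_length))


# ---------------------------------------------------------------------------
# Naive Smith–Waterman with affine gaps (three-state DP, no tricks)
# ---------------------------------------------------------------------------

def naive_sw_score(a: str, b: str, sub, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Local alignment score; a gap of length L costs open + L*extend."""
    NEG = -(10 ** 9)
    n, m = len(a), len(b)
    M = [[0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (moving in a)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(
                M[i - 1][j] - gap_open - gap_extend, Ix[i - 1][j] - gap_extend
            )
            Iy[i][j] = max(
                M[i][j - 1] - gap_open - gap_extend, Iy[i][j - 1] - gap_extend
            )
            s = sub[a[i - 1]][b[j - 1]]
            M[i][j] = max(
                0,
                M[i - 1][j - 1] + s,
                Ix[i - 1][j - 1] + s,
                Iy[i - 1][j - 1] + s,
            )
            best = max(best, M[i][j], Ix[i][j], Iy[i][j])
    return best


def blosum62_dict():
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    return {x: {y: int(m[x][y]) for y in m.alphabet} for x in m.alphabet}


# ---------------------------------------------------------------------------
# Naive global (Needleman–Wunsch) with linear gaps, score only
# ---------------------------------------------------------------------------

def naive_nw_score(a: str, b: str, sub, gap: float) -> float:
    n, m = len(a), len(b)
    D = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        D[i][0] = -gap * i
    for j in range(1, m + 1):
        D[0][j] = -gap * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i][j] = max(
                D[i - 1][j - 1] + sub[a[i - 1]][b[j - 1]],
                D[i - 1][j] - gap,
                D[i][j - 1] - gap,
            )
    return D[n][m]


# ---------------------------------------------------------------------------
# Exhaustive parsimony: enumerate every unrooted topology, score with a
# plain per-column set-based Fitch
# ---------------------------------------------------------------------------

def all_unrooted_topologies(taxa: list[str]):
    """Recursive edge-insertion enumeration; (2n-5)!! topologies."""
    if len(taxa) < 4:
        yield ((taxa[0], taxa[1]), taxa[2]) if len(taxa) == 3 else tuple(taxa)
        return

    def insert_everywhere(tree, x):
        def subs(node, rebuild):
            yield rebuild((node, x))
            if isinstance(node, tuple):
                left, right = node
                yield from subs(left, lambda nl, _r=right: rebuild((nl, _r)))
                yield from subs(right, lambda nr, _l=left: rebuild((_l, nr)))

        l, r = tree
        yield from subs(l, lambda nl: (nl, r))
        yield from subs(r, lambda nr: (l, nr))

    def build(current, remaining):
        if not remaining:
            yield current
            return
        x, rest = remaining[0], remaining[1:]
        seen = set()
        for t in insert_everywhere(current, x):
            key = frozenset(map(frozenset, _bips(t)))
            if key in seen:
                continue
            seen.add(key)
            yield from build(t, rest)

    start = ((taxa[0], taxa[1]), taxa[2])
    yield from build(start, list(taxa[3:]))


def _leafset(node):
    return {node} if isinstance(node, str) else _leafset(node[0]) | _leafset(node[1])


def _bips(tree):
    alls = frozenset(_leafset(tree))
    out = []

    def walk(node):
        s = frozenset(_leafset(node))
        if 2 <= len(s) <= len(alls) - 2:
            out.append(min(s, alls - s, key=lambda x: sorted(x)))
        if isinstance(node, tuple):
            walk(node[0])
            walk(node[1])

    walk(tree[0])
    walk(tree[1])
    return out


def set_fitch_score(tree, rows: dict[str, str]) -> int:
    """Plain per-column Fitch with Python sets; gaps/X = all 20 states."""
    aa = set("ACDEFGHIKLMNPQRSTVWY")
    ncols = len(next(iter(rows.values())))
    total = 0
    for col in range(ncols):
        count = 0

        def down(node):
            nonlocal count
            if isinstance(node, str):
                c = rows[node][col]
                return {c} if c in aa else set(aa)
            s1, s2 = down(node[0]), down(node[1])
            inter = s1 & s2
            if inter:
                return inter
            count += 1
            return s1 | s2

        down(tree)
        total += count
    return total


def exhaustive_min_score(taxa, rows) -> int:
    return min(
        set_fitch_score(t, rows) for t in all_unrooted_topologies(list(taxa))
    )


# ---------------------------------------------------------------------------
# Breakpoint adjacency counting by direct search
# ---------------------------------------------------------------------------

def brute_breakpoints(v1, v2) -> int:
    """Adjacencies of v1 not found in v2 (forward or reversed-negated),
    by scanning v2 for each consecutive pair."""
    common = {abs(x) for x in v1} & {abs(x) for x in v2}
    o1 = [x for x in v1 if abs(x) in common]
    o2 = [x for x in v2 if abs(x) in common]
    missing = 0
    for a, b in zip(o1, o1[1:]):
        found = False
        for c, d in zip(o2, o2[1:]):
            if (c, d) == (a, b) or (c, d) == (-b, -a):
                found = True
                break
        missing += not found
    return missing


def segment_in_vector(seg, vec) -> bool:
    k = len(seg)
    rev = [-x for x in reversed(seg)]
    return any(
        list(vec[i : i + k]) in (list(seg), rev) for i in range(len(vec) - k + 1)
    )
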
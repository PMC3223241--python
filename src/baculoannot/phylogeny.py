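"""Concatenated-gene maximum-parsimony phylogenetics.

Pipeline: per-gene progressive multiple alignment → concatenation into a
partitioned supermatrix → Fitch parsimony scoring → heuristic tree
search (stepwise addition under a seeded random taxon order, followed by
nearest-neighbour-interchange hill climbing, with restarts) → bootstrap
support by column resampling.

Trees are unrooted binary trees over taxon labels, represented
internally as nested 2-tuples with a virtual degree-2 root; the Fitch
score is invariant under the placement of that root.  Gaps and ambiguous
residues are treated as missing data (any state).  All tie-breaking is
deterministic, and stochastic steps take an explicit seed, so repeated
runs are byte-identical.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .errors import InputError

log = logging.getLogger(__name__)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
_FULL_MASK = np.uint32((1 << len(AA_ORDER)) - 1)

#: A tree is a leaf label (str) or a 2-tuple of trees (virtual root).
Tree = "str | tuple"


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------

DEFAULT_GAP_PEN = 8.0


def _pair_scores(matrix_name: str = "BLOSUM62") -> dict[tuple[str, str], float]:
    m = substitution_matrices.load(matrix_name)
    letters = m.alphabet
    return {
        (a, b): float(m[a][b])
        for a in letters
        for b in letters
    }


_B62 = _pair_scores()


def _col_score(col_a: str, col_b: str, gap_pen: float) -> float:
    """Mean sum-of-pairs score between two alignment columns: residue
    pairs score by BLOSUM62, residue-vs-gap by −gap_pen, gap-gap 0."""
    total = 0.0
    for x in col_a:
        for y in col_b:
            if x == "-" and y == "-":
                continue
            if x == "-" or y == "-":
                total -= gap_pen
            else:
                total += _B62.get((x, y), _B62.get((x, "X"), 0.0))
    return total / (len(col_a) * len(col_b))


def _gap_col_score(col: str, gap_pen: float) -> float:
    ng = sum(1 for c in col if c != "-")
    return -gap_pen * ng / len(col)


def align_profiles(
    prof_a: list[str], prof_b: list[str], gap_pen: float = DEFAULT_GAP_PEN
) -> tuple[list[str], list[str]]:
    """Global (Needleman–Wunsch) alignment of two alignment profiles with
    linear gap penalties and deterministic tie-breaking (diagonal over
    up over left).  With two single sequences this is plain NW."""
    cols_a = ["".join(s[i] for s in prof_a) for i in range(len(prof_a[0]))]
    cols_b = ["".join(s[j] for s in prof_b) for j in range(len(prof_b[0]))]
    n, m = len(cols_a), len(cols_b)
    ga = [_gap_col_score(c, gap_pen) for c in cols_a]
    gb = [_gap_col_score(c, gap_pen) for c in cols_b]
    score = np.zeros((n + 1, m + 1))
    move = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    for i in range(1, n + 1):
        score[i, 0] = score[i - 1, 0] + ga[i - 1]
        move[i, 0] = 1
    for j in range(1, m + 1):
        score[0, j] = score[0, j - 1] + gb[j - 1]
        move[0, j] = 2
    for i in range(1, n + 1):
        ca = cols_a[i - 1]
        for j in range(1, m + 1):
            d = score[i - 1, j - 1] + _col_score(ca, cols_b[j - 1], gap_pen)
            u = score[i - 1, j] + ga[i - 1]
            l = score[i, j - 1] + gb[j - 1]
            best = max(d, u, l)
            score[i, j] = best
            move[i, j] = 0 if d == best else (1 if u == best else 2)
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        mv = move[i, j]
        if mv == 0 and i > 0 and j > 0:
            out_a.append(cols_a[i - 1])
            out_b.append(cols_b[j - 1])
            i -= 1
            j -= 1
        elif mv == 1 and i > 0 or j == 0:
            out_a.append(cols_a[i - 1])
            out_b.append("-" * len(prof_b))
            i -= 1
        else:
            out_a.append("-" * len(prof_a))
            out_b.append(cols_b[j - 1])
            j -= 1
    out_a.reverse()
    out_b.reverse()
    new_a = ["".join(c[k] for c in out_a) for k in range(len(prof_a))]
    new_b = ["".join(c[k] for c in out_b) for k in range(len(prof_b))]
    return new_a, new_b


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    if len(a) < k or len(b) < k:
        return 1.0
    from collections import Counter

    ca = Counter(a[i : i + k] for i in range(len(a) - k + 1))
    cb = Counter(b[i : i + k] for i in range(len(b) - k + 1))
    common = sum(min(ca[w], cb[w]) for w in ca)
    return 1.0 - common / min(sum(ca.values()), sum(cb.values()))


def progressive_msa(
    seqs: dict[str, str], gap_pen: float = DEFAULT_GAP_PEN
) -> dict[str, str]:
    """Progressive multiple alignment: UPGMA guide tree from pairwise
    k-mer distances, profiles merged by dynamic programming.  A single
    sequence is returned unchanged."""
    names = sorted(seqs)
    if len(names) == 1:
        return dict(seqs)
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    n = len(names)
    dm = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        dm[i, j] = dm[j, i] = _kmer_distance(seqs[names[i]], seqs[names[j]])
    z = linkage(squareform(dm, checks=False), method="average")
    # cluster id -> (member names, profile rows)
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([names[i]], [seqs[names[i]]]) for i in range(n)
    }
    for step, (ia, ib, _, _) in enumerate(z):
        na, pa = clusters.pop(int(ia))
        nb, pb = clusters.pop(int(ib))
        qa, qb = align_profiles(pa, pb, gap_pen)
        clusters[n + step] = (na + nb, qa + qb)
    members, rows = clusters.popitem()[1]
    return {name: row for name, row in zip(members, rows)}


# ---------------------------------------------------------------------------
# Supermatrix
# ---------------------------------------------------------------------------

@dataclass
class Supermatrix:
    """Concatenated alignment: equal-length rows over taxa, with 0-based
    half-open per-gene partition boundaries."""

    taxa: list[str]
    rows: dict[str, str]
    partitions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        lens = {len(self.rows[t]) for t in self.taxa}
        if len(lens) > 1:
            raise InputError("supermatrix rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.rows[self.taxa[0]]) if self.taxa else 0


def concatenate(alignments: dict[str, dict[str, str]]) -> Supermatrix:
    """Concatenate per-gene alignments into a supermatrix.  Genes are
    taken in canonical (sorted-name) order so the result is independent
    of input ordering; a taxon missing from a gene is padded with gaps;
    a taxon present in no gene is excluded with a warning."""
    genes = sorted(alignments)
    taxa = sorted({t for g in genes for t in alignments[g]})
    present = {t for t in taxa if any(t in alignments[g] for g in genes)}
    dropped = [t for t in taxa if t not in present]
    if dropped:
        log.warning("taxa present in no gene excluded: %s", dropped)
    taxa = [t for t in taxa if t in present]
    rows = {t: [] for t in taxa}
    partitions = []
    pos = 0
    for g in genes:
        aln = alignments[g]
        width = len(next(iter(aln.values()))) if aln else 0
        if not width:
            raise InputError(f"gene {g!r}: empty alignment")
        if len({len(s) for s in aln.values()}) > 1:
            raise InputError(f"gene {g!r}: ragged alignment")
        for t in taxa:
            rows[t].append(aln.get(t, "-" * width))
        partitions.append((g, pos, pos + width))
        pos += width
    return Supermatrix(taxa, {t: "".join(rows[t]) for t in taxa}, partitions)


def trim_columns(sm: Supermatrix, max_gap_frac: float = 0.5) -> Supermatrix:
    """Drop columns with more than ``max_gap_frac`` gaps (partition
    boundaries are recomputed)."""
    arr = np.array([list(sm.rows[t]) for t in sm.taxa])
    gap_frac = (arr == "-").mean(axis=0)
    keep = gap_frac <= max_gap_frac
    new_parts = []
    pos = 0
    for g, lo, hi in sm.partitions:
        w = int(keep[lo:hi].sum())
        if w:
            new_parts.append((g, pos, pos + w))
            pos += w
    rows = {t: "".join(np.array(list(sm.rows[t]))[keep]) for t in sm.taxa}
    return Supermatrix(list(sm.taxa), rows, new_parts)


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------

def leaf_state_masks(sm: Supermatrix) -> dict[str, np.ndarray]:
    """Per-taxon bitmask arrays over columns; gaps/X/unknown = all states
    (missing data)."""
    out = {}
    for t in sm.taxa:
        row = sm.rows[t]
        masks = np.empty(len(row), dtype=np.uint32)
        for i, c in enumerate(row):
            idx = _AA_INDEX.get(c)
            masks[i] = (1 << idx) if idx is not None else _FULL_MASK
        out[t] = masks
    return out


def _fitch(node, masks: dict[str, np.ndarray], changes: np.ndarray) -> np.ndarray:
    if isinstance(node, str):
        return masks[node]
    left = _fitch(node[0], masks, changes)
    right = _fitch(node[1], masks, changes)
    inter = left & right
    empty = inter == 0
    changes[empty] += 1
    return np.where(empty, left | right, inter)


def parsimony_score(
    tree, sm: Supermatrix, weights: np.ndarray | None = None,
    masks: dict[str, np.ndarray] | None = None,
) -> int:
    """Fitch parsimony length of an unrooted tree on the supermatrix
    (column ``weights`` support bootstrap resampling)."""
    if masks is None:
        masks = leaf_state_masks(sm)
    if set(_leaves(tree)) != set(sm.taxa):
        raise InputError("tree leaf set does not match supermatrix taxa")
    changes = np.zeros(sm.n_columns, dtype=np.int64)
    _fitch(tree, masks, changes)
    if weights is None:
        return int(changes.sum())
    return int((changes * weights).sum())


def _score_raw(tree, masks, ncols, weights=None) -> int:
    changes = np.zeros(ncols, dtype=np.int64)
    _fitch(tree, masks, changes)
    return int(changes.sum() if weights is None else (changes * weights).sum())


# ---------------------------------------------------------------------------
# Tree utilities
# ---------------------------------------------------------------------------

def _leaves(tree) -> list[str]:
    if isinstance(tree, str):
        return [tree]
    return _leaves(tree[0]) + _leaves(tree[1])


def bipartitions(tree) -> set[frozenset]:
    """Non-trivial bipartitions of the unrooted tree, each given as the
    frozenset of leaves on the side not containing the reference
    (lexicographically smallest) taxon."""
    all_leaves = frozenset(_leaves(tree))
    ref = min(all_leaves)
    out: set[frozenset] = set()

    def walk(node):
        if isinstance(node, str):
            return frozenset([node])
        below = walk(node[0]) | walk(node[1])
        side = all_leaves - below if ref in below else below
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(side)
        return below

    walk(tree)
    return out


def canonical_newick(tree, supports: dict[frozenset, float] | None = None) -> str:
    """Canonical Newick string of the unrooted topology: rooted on the
    lexicographically smallest leaf, children sorted by their own
    canonical string.  ``supports`` (bipartition → percent) are written
    as internal node labels."""
    all_leaves = frozenset(_leaves(tree))
    if len(all_leaves) == 1:
        return f"{next(iter(all_leaves))};"
    ref = min(all_leaves)
    adj = _adjacency(tree)
    ref_node = ("leaf", ref)
    (parent,) = adj[ref_node]

    def build(node, come_from) -> str:
        if node[0] == "leaf":
            return node[1]
        kids = [n for n in adj[node] if n != come_from]
        parts = sorted(build(k, node) for k in kids)
        label = ""
        if supports is not None:
            below = frozenset(_leaves_of(node, come_from, adj))
            side = below if ref not in below else all_leaves - below
            if side in supports:
                label = f"{supports[side]:g}"
        return "(" + ",".join(parts) + ")" + label

    return f"({ref},{build(parent, ref_node)});"


def _adjacency(tree):
    """Unrooted adjacency map over hashable node keys (virtual root
    suppressed).  Leaves are ('leaf', name); internal nodes ('int', id)."""
    adj: dict = {}
    counter = itertools.count()

    def key(node):
        return ("leaf", node) if isinstance(node, str) else ("int", next(counter))

    def walk(node, nkey):
        if isinstance(node, str):
            return
        for child in node:
            ckey = key(child)
            adj.setdefault(nkey, []).append(ckey)
            adj.setdefault(ckey, []).append(nkey)
            walk(child, ckey)

    root = ("int", next(counter))
    walk(tree, root)
    if len(adj.get(root, [])) == 2:
        a, b = adj.pop(root)
        adj[a] = [x for x in adj[a] if x != root] + [b]
        adj[b] = [x for x in adj[b] if x != root] + [a]
    return adj


def _leaves_of(node, come_from, adj) -> list[str]:
    if node[0] == "leaf":
        return [node[1]]
    out = []
    for n in adj[node]:
        if n != come_from:
            out.extend(_leaves_of(n, node, adj))
    return out


def nni_neighbors(tree) -> list:
    """All trees one nearest-neighbour interchange away (every internal
    edge of the unrooted topology, two rearrangements each)."""
    out = []
    l, r = tree
    if isinstance(l, tuple) and isinstance(r, tuple):
        (a, b), (c, d) = l, r
        out.append(((a, c), (b, d)))
        out.append(((a, d), (b, c)))

    def walk(node, rebuild):
        if isinstance(node, str):
            return
        x, y = node
        if isinstance(x, tuple):
            p, q = x
            out.append(rebuild(((p, y), q)))
            out.append(rebuild(((q, y), p)))
        if isinstance(y, tuple):
            p, q = y
            out.append(rebuild(((p, x), q)))
            out.append(rebuild(((q, x), p)))
        walk(x, lambda nx: rebuild((nx, y)))
        walk(y, lambda ny: rebuild((x, ny)))

    walk(l, lambda nl: (nl, r))
    walk(r, lambda nr: (l, nr))
    return out


def _insertions(tree, taxon: str) -> list:
    """All trees obtained by attaching ``taxon`` onto an edge."""
    out = []

    def walk(node, rebuild):
        out.append(rebuild((node, taxon)))
        if isinstance(node, tuple):
            x, y = node
            walk(x, lambda nx: rebuild((nx, y)))
            walk(y, lambda ny: rebuild((x, ny)))

    x, y = tree
    walk(x, lambda nx: (nx, y))
    walk(y, lambda ny: (x, ny))
    return out


# ---------------------------------------------------------------------------
# Tree search
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """An unrooted parsimony tree with optional bootstrap supports
    (percent per non-trivial bipartition)."""

    tree: object
    taxa: list[str]
    score: int
    supports: dict[frozenset, float] | None = None

    def newick(self) -> str:
        return canonical_newick(self.tree, self.supports)


def _search_one(order: list[str], masks, ncols, weights) -> tuple[int, object]:
    tree = ((order[0], order[1]), order[2])
    for taxon in order[3:]:
        cands = _insertions(tree, taxon)
        scored = [( _score_raw(t, masks, ncols, weights), i) for i, t in enumerate(cands)]
        best = min(scored)
        tree = cands[best[1]]
    score = _score_raw(tree, masks, ncols, weights)
    improved = True
    while improved:
        improved = False
        for cand in nni_neighbors(tree):
            s = _score_raw(cand, masks, ncols, weights)
            if s < score:
                tree, score = cand, s
                improved = True
                break
    return score, tree


def search_mp(
    sm: Supermatrix,
    seed: int = 0,
    restarts: int = 10,
    weights: np.ndarray | None = None,
    masks: dict[str, np.ndarray] | None = None,
) -> PhyloTree:
    """Heuristic maximum-parsimony search: seeded random-order stepwise
    addition plus NNI hill climbing, best of ``restarts`` starts.  Ties
    between equally parsimonious results are broken by canonical Newick
    string order, so the result is deterministic under a fixed seed."""
    taxa = list(sm.taxa)
    if masks is None:
        masks = leaf_state_masks(sm)
    if len(taxa) < 4:
        if len(taxa) == 3:
            tree = ((taxa[0], taxa[1]), taxa[2])
        elif len(taxa) == 2:
            tree = (taxa[0], taxa[1])
        else:
            raise InputError("search_mp needs at least 2 taxa")
        return PhyloTree(tree, taxa, parsimony_score(tree, sm, weights, masks))
    rng = np.random.default_rng(seed)
    best: tuple[int, str, object] | None = None
    for _ in range(restarts):
        order = [taxa[i] for i in rng.permutation(len(taxa))]
        score, tree = _search_one(order, masks, sm.n_columns, weights)
        key = (score, canonical_newick(tree))
        if best is None or key < best[:2]:
            best = (score, key[1], tree)
    return PhyloTree(best[2], taxa, best[0])


def bootstrap(
    sm: Supermatrix,
    focal: PhyloTree,
    replicates: int = 100,
    seed: int = 0,
    restarts: int = 2,
) -> dict[frozenset, float]:
    """Bootstrap supports for the focal tree's bipartitions: columns are
    resampled with replacement per replicate, the search rerun, and each
    bipartition's support is the percentage of replicate best trees that
    contain it.  Reproducible under a fixed seed."""
    if replicates < 1:
        raise InputError("replicates must be ≥ 1")
    masks = leaf_state_masks(sm)
    focal_bips = bipartitions(focal.tree)
    counts = {bip: 0 for bip in focal_bips}
    rng = np.random.default_rng(seed)
    ncols = sm.n_columns
    if ncols and all(
        sm.rows[t] == sm.rows[sm.taxa[0]] for t in sm.taxa
    ):
        log.warning("zero-variation supermatrix: bootstrap supports are degenerate")
    for rep in range(replicates):
        weights = np.bincount(
            rng.integers(0, ncols, size=ncols), minlength=ncols
        ).astype(np.int64)
        rep_tree = search_mp(
            sm, seed=int(rng.integers(0, 2**31 - 1)), restarts=restarts,
            weights=weights, masks=masks,
        )
        rep_bips = bipartitions(rep_tree.tree)
        for bip in focal_bips:
            if bip in rep_bips:
                counts[bip] += 1
    return {bip: 100.0 * c / replicates for bip, c in counts.items()}


def infer_tree(
    gene_seqs: dict[str, dict[str, str]],
    seed: int = 0,
    restarts: int = 10,
    replicates: int = 100,
    trim_gap_frac: float | None = None,
) -> PhyloTree:
    """End-to-end inference: per-gene progressive MSA, concatenation,
    parsimony search, bootstrap.  ``gene_seqs`` maps gene → taxon →
    protein sequence."""
    alignments = {g: progressive_msa(s) for g, s in gene_seqs.items()}
    sm = concatenate(alignments)
    if trim_gap_frac is not None:
        sm = trim_columns(sm, trim_gap_frac)
    tree = search_mp(sm, seed=seed, restarts=restarts)
    if replicates and len(sm.taxa) >= 4:
        tree.supports = bootstrap(sm, tree, replicates=replicates, seed=seed + 1)
    return tree
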
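"""Whole-genome dot plots and gene-order conservation analysis.

The dot plot is exact shared-word (k-mer) matching on both strands, the
desk equivalent of the classic matrix plot used to reveal co-linearity
between related genomes.

Gene-order analysis follows the gene-order-diagram (GOD) approach: each
genome is reduced to a signed vector of reference-gene indices (sign =
strand relative to the anchored focal genome), and conserved runs are
maximal blocks of reference genes that appear consecutively, in the same
order and relative orientation — or uniformly reversed — in every genome
of the panel.  The breakpoint distance counts signed adjacencies present
in one vector but not the other; it is zero exactly for identical or
globally reversed orders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import revcomp
from .errors import InputError
from .homology import OrthologTable


# ---------------------------------------------------------------------------
# Dot plot
# ---------------------------------------------------------------------------

@dataclass
class DotPlot:
    word_size: int
    len_a: int
    len_b: int
    matches: list[tuple[int, int, int]] = field(default_factory=list)
    # (posA, posB, strand): 1-based start of an exact shared word; strand
    # +1 = same strand, -1 = word in A matches revcomp word in B.


def dotplot(seq_a: str, seq_b: str, word_size: int = 8) -> DotPlot:
    """Every exact shared word of ``word_size`` nt between two sequences,
    on both strands."""
    if word_size < 4:
        raise InputError("word_size must be ≥ 4")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    index: dict[str, list[int]] = {}
    for i in range(len(seq_a) - word_size + 1):
        index.setdefault(seq_a[i : i + word_size], []).append(i + 1)
    matches: list[tuple[int, int, int]] = []
    for j in range(len(seq_b) - word_size + 1):
        w = seq_b[j : j + word_size]
        for i in index.get(w, ()):
            matches.append((i, j + 1, 1))
        rc = revcomp(w)
        if rc != w:
            for i in index.get(rc, ()):
                matches.append((i, j + 1, -1))
        else:  # palindromic word: matches both strands at once
            for i in index.get(w, ()):
                matches.append((i, j + 1, -1))
    matches.sort()
    return DotPlot(word_size, len(seq_a), len(seq_b), matches)


def dotplot_to_tsv(dp: DotPlot, path) -> None:
    with open(path, "w") as fh:
        fh.write("pos_a\tpos_b\tstrand\n")
        for i, j, s in dp.matches:
            fh.write(f"{i}\t{j}\t{'+' if s == 1 else '-'}\n")


def plot_dotplot(dp: DotPlot, path, title: str = "") -> None:
    """Render the dot plot to an image file (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for strand, color in ((1, "black"), (-1, "red")):
        xs = [i for i, _, s in dp.matches if s == strand]
        ys = [j for _, j, s in dp.matches if s == strand]
        ax.plot(xs, ys, ".", ms=1, color=color, rasterized=True)
    ax.set_xlim(0, dp.len_a)
    ax.set_ylim(0, dp.len_b)
    ax.set_xlabel("genome A (nt)")
    ax.set_ylabel("genome B (nt)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Gene order vectors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneOrderVector:
    """Signed order of reference genes along one genome.  Entries are
    ±(i+1) where i indexes the focal gene list; the sign is the strand
    relative to the anchored focal genome.  Each gene appears at most
    once."""

    genome_id: str
    order: tuple[int, ...]

    def __post_init__(self):
        seen = {abs(x) for x in self.order}
        if len(seen) != len(self.order) or 0 in seen:
            raise InputError("gene order vector entries must be unique and nonzero")


def gene_order_vector(
    table: OrthologTable, genome_id: str, focal_genes: list[str] | None = None
) -> GeneOrderVector:
    """Project one genome of an ortholog table onto a signed gene-order
    vector over the focal gene list (default: all focal genes)."""
    genes = focal_genes if focal_genes is not None else table.genes
    entries = []
    for gi, gene in enumerate(genes, start=1):
        cell = table.get(gene, genome_id)
        if cell is not None:
            entries.append((cell.order_index, gi * (1 if cell.strand >= 0 else -1)))
    entries.sort()
    return GeneOrderVector(genome_id, tuple(sign for _, sign in entries))


def focal_order_vector(table: OrthologTable, focal_genes: list[str] | None = None) -> GeneOrderVector:
    genes = focal_genes if focal_genes is not None else table.genes
    return GeneOrderVector(table.focal_id, tuple(range(1, len(genes) + 1)))


# ---------------------------------------------------------------------------
# Conserved runs
# ---------------------------------------------------------------------------

def _restrict(v: GeneOrderVector, keep: set[int]) -> tuple[int, ...]:
    return tuple(x for x in v.order if abs(x) in keep)


def _block_present(block: tuple[int, ...], order: tuple[int, ...]) -> bool:
    """Is ``block`` a contiguous sub-run of ``order``, either as-is or
    reversed with flipped signs?"""
    k = len(block)
    rev = tuple(-x for x in reversed(block))
    for i in range(len(order) - k + 1):
        seg = order[i : i + k]
        if seg == block or seg == rev:
            return True
    return False


def conserved_runs(vectors: list[GeneOrderVector]) -> list[list[int]]:
    """Maximal runs of reference genes shared by all vectors in order.

    Genes absent from any genome are dropped first (analysis restricted
    to the shared gene subset).  A run is reported in the order of the
    first (focal) vector, as unsigned gene indices; it is present in a
    genome if it occurs there as a contiguous block in the same signed
    order or globally reversed."""
    if len(vectors) < 2:
        raise InputError("conserved_runs requires at least two vectors")
    shared = set.intersection(*({abs(x) for x in v.order} for v in vectors))
    if not shared:
        return []
    focal = _restrict(vectors[0], shared)
    others = [_restrict(v, shared) for v in vectors[1:]]
    runs: list[list[int]] = []
    i = 0
    n = len(focal)
    while i < n:
        j = i
        while j + 1 < n and all(
            _block_present(focal[i : j + 2], o) for o in others
        ):
            j += 1
        runs.append([abs(x) for x in focal[i : j + 1]])
        i = j + 1
    return runs


# ---------------------------------------------------------------------------
# Breakpoint distance
# ---------------------------------------------------------------------------

def _adjacencies(order: tuple[int, ...]) -> set[tuple[int, int]]:
    out = set()
    for a, b in zip(order, order[1:]):
        out.add(min((a, b), (-b, -a)))  # orientation-canonical adjacency
    return out


def breakpoint_distance(v1: GeneOrderVector, v2: GeneOrderVector) -> int:
    """Number of signed adjacencies of v1 (restricted to the shared gene
    set) absent from v2.  Zero iff the restricted orders are identical up
    to global reversal; symmetric because both restrictions have equal
    length."""
    common = {abs(x) for x in v1.order} & {abs(x) for x in v2.order}
    if not common:
        raise InputError("breakpoint distance undefined: no shared genes")
    o1, o2 = _restrict(v1, common), _restrict(v2, common)
    return len(_adjacencies(o1) - _adjacencies(o2))
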
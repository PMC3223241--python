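"""Protein similarity engine: exact local alignment, reciprocal best
hits (RBH) as an orthology proxy, and presence/absence gene
classification over a genome panel.

Alignment uses Smith–Waterman with affine gaps (BLOSUM62, gap open 11,
gap extend 1 — the conventional BLASTP parameter set).  A gap of length
L costs ``open + L·extend``.  Percent identity is computed over aligned
columns only (gap columns excluded), matching how pairwise identities
are conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import InputError

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
DEFAULT_MIN_SCORE = 50
DEFAULT_MIN_ALN_LEN = 30


@dataclass(frozen=True)
class AlignmentResult:
    """Optimal local protein alignment summary."""

    score: int
    identity_pct: float  # over aligned (both-residue) columns
    aligned_len: int  # columns in the local alignment, gaps included
    range_a: tuple[int, int]  # 1-based inclusive on sequence a
    range_b: tuple[int, int]


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    aln.substitution_matrix = substitution_matrices.load(matrix)
    # affine cost open + L*extend: first gap position costs open+extend
    aln.open_gap_score = -(gap_open + gap_extend)
    aln.extend_gap_score = -gap_extend
    return aln


def _check_protein(seq: str, label: str) -> str:
    if not seq:
        raise InputError(f"empty protein sequence for {label!r}")
    s = seq.upper()
    bad = set(s) - PROTEIN_ALPHABET
    if bad:
        raise InputError(f"{label!r}: invalid residues {sorted(bad)}")
    return s


def align_local(
    a: str,
    b: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal Smith–Waterman local alignment of two proteins."""
    a = _check_protein(a, "a")
    b = _check_protein(b, "b")
    aligner = _aligner(matrix, gap_open, gap_extend)
    alns = aligner.align(a, b)
    if len(alns) == 0 or alns.score <= 0:
        return AlignmentResult(0, 0.0, 0, (0, 0), (0, 0))
    aln = alns[0]
    blocks_a, blocks_b = aln.aligned
    matches = 0
    residue_cols = 0
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        residue_cols += ea - sa
        matches += sum(1 for x, y in zip(a[sa:ea], b[sb:eb]) if x == y)
    a_lo, a_hi = int(blocks_a[0][0]), int(blocks_a[-1][1])
    b_lo, b_hi = int(blocks_b[0][0]), int(blocks_b[-1][1])
    gap_cols = (a_hi - a_lo - residue_cols) + (b_hi - b_lo - residue_cols)
    identity = 100.0 * matches / residue_cols if residue_cols else 0.0
    return AlignmentResult(
        score=int(round(aln.score)),
        identity_pct=float(identity),
        aligned_len=int(residue_cols + gap_cols),
        range_a=(a_lo + 1, a_hi),
        range_b=(b_lo + 1, b_hi),
    )


# ---------------------------------------------------------------------------
# Reciprocal best hits
# ---------------------------------------------------------------------------

def _best_hits(
    queries: dict[str, str],
    targets: dict[str, str],
    scores: dict[tuple[str, str], AlignmentResult],
) -> dict[str, str]:
    """query -> unique best target (absent if the best score is tied)."""
    best: dict[str, str] = {}
    for q in queries:
        ranked = sorted(
            ((scores[q, t].score, t) for t in targets), key=lambda st: (-st[0], st[1])
        )
        if not ranked:
            continue
        if len(ranked) > 1 and ranked[0][0] == ranked[1][0]:
            continue  # ambiguous best hit
        best[q] = ranked[0][1]
    return best


def reciprocal_best_hits(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    min_score: int = DEFAULT_MIN_SCORE,
    min_aln_len: int = DEFAULT_MIN_ALN_LEN,
    **align_params,
) -> list[tuple[str, str]]:
    """Pairs (a, b) such that b is a's unique best hit in proteome_b and
    vice versa, with score ≥ ``min_score`` and ≥ ``min_aln_len`` aligned
    columns.  Output is sorted by the a-side name, so the result is
    independent of input ordering."""
    if not proteome_a or not proteome_b:
        return []
    scores: dict[tuple[str, str], AlignmentResult] = {}
    for qa, sa in proteome_a.items():
        for qb, sb in proteome_b.items():
            scores[qa, qb] = align_local(sa, sb, **align_params)
    fwd = _best_hits(proteome_a, proteome_b, scores)
    rev = _best_hits(
        proteome_b, proteome_a, {(b, a): r for (a, b), r in scores.items()}
    )
    pairs = []
    for qa, qb in fwd.items():
        res = scores[qa, qb]
        if (
            rev.get(qb) == qa
            and res.score >= min_score
            and res.aligned_len >= min_aln_len
        ):
            pairs.append((qa, qb))
    return sorted(pairs)


# ---------------------------------------------------------------------------
# Ortholog table over a genome panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrthologCell:
    ortholog: str
    order_index: int  # 0-based rank of the ortholog along its genome
    strand: int  # relative to the anchored orientation of that genome
    score: int = 0
    identity_pct: float = 0.0


@dataclass
class OrthologTable:
    """Reference (focal) genes × genomes matrix of ortholog assignments.

    Each cell holds the ortholog's name, its order index along its own
    genome, and its strand sign; a gene absent from a genome has no
    cell.  Orthologs are one-to-one within a genome by construction
    (reciprocal best hits)."""

    focal_id: str
    genes: list[str]  # focal gene names, genome order
    genomes: list[str]
    cells: dict[tuple[str, str], OrthologCell] = field(default_factory=dict)

    def get(self, gene: str, genome: str) -> OrthologCell | None:
        return self.cells.get((gene, genome))

    def presence(self, gene: str) -> set[str]:
        return {g for g in self.genomes if (gene, g) in self.cells}


def _ordered_proteome(record) -> tuple[dict[str, str], dict[str, tuple[int, int]]]:
    from .genome_io import extract_proteins, sort_orfs

    order = {
        f.name: (i, f.strand)
        for i, f in enumerate(sort_orfs(record.features, len(record)))
    }
    prots = {name: seq for name, seq in extract_proteins(record) if seq}
    return prots, order


def build_ortholog_table(
    focal, panel, min_score: int = DEFAULT_MIN_SCORE,
    min_aln_len: int = DEFAULT_MIN_ALN_LEN, **align_params
) -> OrthologTable:
    """RBH-based ortholog table of a focal genome against each genome of
    a panel (all :class:`~baculoannot.genome_io.GenomeRecord`)."""
    focal_prots, focal_order = _ordered_proteome(focal)
    genes = sorted(focal_prots, key=lambda n: focal_order[n][0])
    table = OrthologTable(focal.id, genes, [g.id for g in panel])
    for genome in panel:
        prots, order = _ordered_proteome(genome)
        pairs = reciprocal_best_hits(
            focal_prots, prots, min_score, min_aln_len, **align_params
        )
        for ga, gb in pairs:
            res = align_local(focal_prots[ga], prots[gb], **align_params)
            idx, strand = order[gb]
            # strand sign relative to the focal gene's own orientation
            rel = strand * focal_order[ga][1]
            table.cells[ga, genome.id] = OrthologCell(
                gb, idx, rel, res.score, res.identity_pct
            )
    return table


# ---------------------------------------------------------------------------
# Gene classification
# ---------------------------------------------------------------------------

def classify_genes(
    table: OrthologTable, group_labels: dict[str, str]
) -> dict[str, str]:
    """Label each focal gene by its phylogenetic distribution over the
    panel: ``core`` (present in every panel genome), ``group-specific``
    (present in all genomes of exactly one group and in no other),
    ``unique`` (present in the focal genome only), else
    ``shared-subset``."""
    missing = [g for g in table.genomes if g not in group_labels]
    if missing:
        raise InputError(f"no group label for genomes: {missing}")
    groups: dict[str, set[str]] = {}
    for genome, grp in group_labels.items():
        if genome in table.genomes:
            groups.setdefault(grp, set()).add(genome)
    out: dict[str, str] = {}
    for gene in table.genes:
        present = table.presence(gene)
        if not present:
            out[gene] = "unique"
        elif present == set(table.genomes):
            out[gene] = "core"
        else:
            full_groups = [g for g, members in groups.items() if members <= present]
            covered = set().union(*(groups[g] for g in full_groups)) if full_groups else set()
            if len(full_groups) == 1 and present == covered:
                out[gene] = "group-specific"
            else:
                out[gene] = "shared-subset"
    return out
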
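"""Planted-truth simulators: single circular genomes with known ORFs and
promoter motifs, and genome panels diverged along a known tree with
known orthology and gene-order rearrangements.

The genome simulator emulates the structure of a small AT-rich circular
dsDNA virus genome (a granulovirus-like genome: ~80–180 kb, 54–68% A+T,
100–180 mostly non-overlapping ORFs of ≥150 nt on both strands, with
early/late promoter motifs planted upstream of a subset of ORFs).
Background sequence is i.i.d. with base probabilities solving the A+T
target; planted coding regions draw codons biased to the same
composition.  After planting, a cleanup pass mutates background (spacer)
bases to break any chance ORF that would survive greedy selection, so
the selected ORF set of a simulated genome equals the planted truth
exactly — which is what makes every downstream stage scorable.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ._seq import CODON_TABLE, STOP_CODONS, revcomp
from .errors import FeasibilityError, InputError
from .genome_io import GenomeRecord, OrfAnnotation, OrfSet, sort_orfs
from .orfs import MAX_OVERLAP_DEFAULT, MIN_CODONS_DEFAULT, enumerate_orfs, select_orfs
from .promoters import MotifHit, PromoterCall

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study-scale defaults: a ~124 kb circular genome at 61% A+T with
    130 planted non-overlapping ORFs (≈86% coding), forward:reverse
    strand ratio ≈ the 77:56 split typical of these genomes, and
    early/late promoter motifs planted upstream of most ORFs."""

    genome_length: int = 124_000
    at_target: float = 61.0  # percent
    n_orfs: int = 130
    orf_length_range: tuple[int, int] = (300, 1302)  # nt incl. stop
    fraction_reverse: float = 0.42
    max_planted_overlap: int = 0
    late_rate: float = 0.55  # probability of planting a late motif
    early_rate: float = 0.30  # ... an early TATA+initiator pair
    min_spacer: int = 60
    min_codons: int = MIN_CODONS_DEFAULT
    max_overlap_bp: int = MAX_OVERLAP_DEFAULT
    clean_background: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name, rate in (
            ("fraction_reverse", self.fraction_reverse),
            ("late_rate", self.late_rate),
            ("early_rate", self.early_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise FeasibilityError(f"{name} must lie in [0, 1]")
        if self.late_rate + self.early_rate > 1.0:
            raise FeasibilityError("late_rate + early_rate must be ≤ 1")
        if self.genome_length <= 0 or self.n_orfs < 0:
            raise FeasibilityError("lengths and counts must be positive")
        if self.max_planted_overlap != 0:
            # overlapping planted coding regions would need bases satisfying
            # two reading frames at once; only disjoint planting is supported
            raise FeasibilityError("only max_planted_overlap=0 is supported")
        lo, hi = self.orf_length_range
        if lo < 3 * self.min_codons or hi < lo or lo % 3 or hi % 3:
            raise FeasibilityError(
                "orf_length_range must be multiples of 3 and ≥ 3×min_codons"
            )


def _base_probs(at_target: float) -> tuple[list[str], np.ndarray]:
    at = at_target / 100.0
    return list("ATGC"), np.array([at / 2, at / 2, (1 - at) / 2, (1 - at) / 2])


def _codon_tables(at_target: float):
    """Non-stop codons and stop codons with composition-matched weights."""
    bases, probs = _base_probs(at_target)
    p = dict(zip(bases, probs))
    codons = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
    sense = [c for c in codons if c not in STOP_CODONS]
    w_sense = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in sense])
    stops = sorted(STOP_CODONS)
    w_stop = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in stops])
    return sense, w_sense / w_sense.sum(), stops, w_stop / w_stop.sum()


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

@dataclass
class GenomeTruth:
    orfs: OrfSet
    promoters: list[PromoterCall]


class _Builder:
    """Mutable genome under construction, with position protection."""

    def __init__(self, length: int):
        self.seq = np.empty(length, dtype="<U1")
        self.protected = np.zeros(length, dtype=bool)  # planted, never touch
        self.committed = np.zeros(length, dtype=bool)  # cleanup writes
        self.length = length

    def write(self, pos1: int, bases: str, protect: bool = False) -> None:
        for k, b in enumerate(bases):
            i = (pos1 - 1 + k) % self.length
            self.seq[i] = b
            if protect:
                self.protected[i] = True

    def to_str(self) -> str:
        return "".join(self.seq)


def _orf_sequence(rng, length_nt, sense, w_sense, stops, w_stop) -> str:
    n_codons = length_nt // 3
    body = rng.choice(len(sense), size=n_codons - 2, p=w_sense)
    return (
        "ATG" + "".join(sense[i] for i in body) + stops[rng.choice(len(stops), p=w_stop)]
    )


def _upstream_positions(orf: OrfAnnotation, genome_length: int, offset: int) -> int:
    """1-based genomic position of the base ``offset`` nt upstream of the
    ATG on the ORF's coding strand (offset 1 = adjacent base)."""
    if orf.strand == 1:
        return (orf.start - 1 - offset) % genome_length + 1
    return (orf.start - 1 + offset) % genome_length + 1


def _write_motif(builder: _Builder, orf: OrfAnnotation, offset: int, motif: str) -> None:
    """Write ``motif`` so that, read 5'→3' on the ORF's coding strand, it
    starts ``offset`` nt upstream of the ATG."""
    for t, ch in enumerate(motif):
        pos = _upstream_positions(orf, builder.length, offset - t)
        base = ch if orf.strand == 1 else _COMPLEMENT[ch]
        builder.write(pos, base, protect=True)


def simulate_genome(config: SimulationConfig) -> tuple[GenomeRecord, GenomeTruth]:
    """Simulate a circular genome with planted ORFs and promoter motifs;
    returns the record (features = planted truth) and the truth object.

    Rarely, a chance reading frame through a planted gene cannot be
    broken without touching planted bases; such draws are rejected and
    the genome redrawn from a seed derived deterministically from the
    configured one, so output remains a pure function of the seed."""
    config.validate()
    last_error: FeasibilityError | None = None
    for attempt in range(8):
        rng = np.random.default_rng([config.seed, attempt])
        try:
            return _simulate_genome_once(config, rng)
        except _CleanupCollision as exc:
            last_error = FeasibilityError(str(exc))
    raise last_error


class _CleanupCollision(Exception):
    """Internal: a planted/chance reading-frame collision that cleanup
    cannot resolve; triggers a redraw."""


def _simulate_genome_once(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[GenomeRecord, GenomeTruth]:
    L = config.genome_length
    bases, bprobs = _base_probs(config.at_target)
    sense, w_sense, stops, w_stop = _codon_tables(config.at_target)

    lo, hi = config.orf_length_range
    lengths = rng.integers(lo // 3, hi // 3 + 1, size=config.n_orfs) * 3
    total = int(lengths.sum())
    slack = L - total - config.n_orfs * config.min_spacer
    if config.n_orfs and slack < 0:
        raise FeasibilityError(
            f"planted ORFs ({total} nt) plus spacers exceed genome length {L}"
        )

    builder = _Builder(L)
    # background everywhere first; ORFs overwrite their slots
    builder.write(1, "".join(rng.choice(bases, size=L, p=bprobs)))

    orfs: OrfSet = []
    if config.n_orfs:
        extra = rng.multinomial(slack, np.full(config.n_orfs, 1 / config.n_orfs))
        spacers = extra + config.min_spacer
        cursor = 1  # 1-based leftmost unused position
        for i in range(config.n_orfs):
            cursor += int(spacers[i])
            length = int(lengths[i])
            seq = _orf_sequence(rng, length, sense, w_sense, stops, w_stop)
            strand = -1 if rng.random() < config.fraction_reverse else 1
            left = cursor
            if strand == -1:
                builder.write(left, revcomp(seq), protect=True)
                start = left + length - 1
            else:
                builder.write(left, seq, protect=True)
                start = left
            orfs.append(OrfAnnotation.from_start("", start, strand, length, L))
            cursor += length
    orfs = sort_orfs(orfs, L)
    orfs = [
        OrfAnnotation(f"ORF{i + 1}", f.start, f.end, f.strand, f.length_nt, f.wraps)
        for i, f in enumerate(orfs)
    ]

    # plant promoter motifs in the spacer upstream of each ORF
    promoters: list[PromoterCall] = []
    for i, orf in enumerate(orfs):
        avail = _free_upstream(builder, orf, limit=110)
        r = rng.random()
        if r < config.late_rate and avail >= 14:
            d = "AGT"[rng.integers(0, 3)]
            motif = d + "TAAG"
            off = int(rng.integers(9, min(avail, 110) - 4 + 1))
            _write_motif(builder, orf, off, motif)
            promoters.append(
                PromoterCall(orf.name, "late", [MotifHit("late", off, motif)])
            )
        elif r < config.late_rate + config.early_rate and avail >= 40:
            o1 = int(rng.integers(34, min(avail, 105) + 1))
            _write_motif(builder, orf, o1, "TATAA")
            _write_motif(builder, orf, o1 - 25, "CAGT")
            promoters.append(
                PromoterCall(orf.name, "early", [MotifHit("early", o1, "TATAA")])
            )
        else:
            promoters.append(PromoterCall(orf.name, "none", []))

    record = GenomeRecord("sim", builder.to_str(), circular=True, features=list(orfs))
    if config.clean_background and config.n_orfs:
        record = _clean_background(record, orfs, builder, config)
    truth = GenomeTruth(orfs=list(orfs), promoters=promoters)
    record.features = list(orfs)
    return record, truth


def _free_upstream(builder: _Builder, orf: OrfAnnotation, limit: int) -> int:
    """Contiguous unprotected run length immediately upstream of the ORF
    (coding strand), capped at ``limit``."""
    for off in range(1, limit + 1):
        pos = _upstream_positions(orf, builder.length, off)
        if builder.protected[pos - 1]:
            return off - 1
    return limit


def _clean_background(
    record: GenomeRecord, planted: OrfSet, builder: _Builder, config: SimulationConfig
) -> GenomeRecord:
    """Mutate unprotected bases until greedy ORF selection returns
    exactly the planted set: chance background ORFs are broken by
    writing stops (or breaking start codons) in their spacer-resident
    bases, and a planted ORF shadowed by an upstream in-frame ATG is
    freed by breaking the extension."""
    planted_keys = {(f.start, f.strand, f.length_nt) for f in planted}
    L = len(record)
    for _ in range(120):
        cands = enumerate_orfs(record, config.min_codons)
        selected = select_orfs(cands, L, config.max_overlap_bp)
        sel_keys = {(f.start, f.strand, f.length_nt) for f in selected}
        if sel_keys == planted_keys:
            return record
        targets = [
            f for f in selected
            if (f.start, f.strand, f.length_nt) not in planted_keys
        ]
        # a missing planted ORF whose shadowing candidate was itself
        # rejected: break the candidate's upstream extension instead
        by_stop = {(c.strand, c.end): c for c in cands}
        for start, strand, length in planted_keys - sel_keys:
            ref = OrfAnnotation.from_start("", start, strand, length, L)
            cand = by_stop.get((strand, ref.end))
            if cand is not None and cand.length_nt > length:
                ext_len = cand.length_nt - length
                targets.append(
                    OrfAnnotation.from_start("", cand.start, strand, ext_len, L)
                )
        progressed = sum(_disrupt(builder, f, L) for f in targets)
        if not progressed:
            raise _CleanupCollision(
                "background cleanup stalled: no chance ORF is disruptable"
            )
        record = GenomeRecord(record.id, builder.to_str(), True, list(planted))
    raise _CleanupCollision("background cleanup did not converge")


def _context_counts(builder: _Builder, positions) -> tuple[int, int]:
    """ATG (forward) and CAT (reverse-strand ATG) occurrences in the
    5-base contexts around each written position."""
    atg = cat = 0
    for p in positions:
        c = "".join(builder.seq[(p + d) % builder.length] for d in range(-2, 3))
        atg += c.count("ATG")
        cat += c.count("CAT")
    return atg, cat


def _try_writes(builder: _Builder, writes, require_safe: bool) -> bool:
    """Apply (0-based position, base) writes; in safe mode revert if a
    new start codon appears on either strand around the written bases
    (it could shadow a planted ORF).  Successful writes are committed so
    later disruptions do not undo them."""
    positions = [p for p, _ in writes]
    before = _context_counts(builder, positions)
    backup = [(p, str(builder.seq[p])) for p in positions]
    for p, b in writes:
        builder.seq[p] = b
    if require_safe:
        after = _context_counts(builder, positions)
        if after[0] > before[0] or after[1] > before[1]:
            for p, b in backup:
                builder.seq[p] = b
            return False
    for p in positions:
        builder.committed[p] = True
    return True


def _disrupt(builder: _Builder, orf: OrfAnnotation, L: int) -> bool:
    """Break a chance ORF without touching protected (planted) bases.

    Preference order: write a stop into a fully free internal codon
    (checked not to create a new start codon); break the ORF's own start
    codon; flip any free base; finally retry all of it without the
    safety check and, in desperation, allow overwriting earlier cleanup
    writes.  Returns False only if every base is planted-protected."""
    n_codons = orf.length_nt // 3

    def positions(ci: int) -> list[int]:
        return [(orf.start - 1 + orf.strand * (3 * ci + t)) % L for t in range(3)]

    def stop_writes(pos):
        stop = "TAA"
        if orf.strand == 1:
            return list(zip(pos, stop))
        return [(p, _COMPLEMENT[b]) for p, b in zip(pos, stop)]

    def flip(p):
        return [(p, "C" if builder.seq[p] != "C" else "G")]

    def free(p, allow_committed):
        if builder.protected[p]:
            return False
        return allow_committed or not builder.committed[p]

    for require_safe, allow_committed in ((True, False), (False, False)):
        for ci in range(1, max(1, n_codons - 1)):
            pos = positions(ci)
            if all(free(p, allow_committed) for p in pos):
                if _try_writes(builder, stop_writes(pos), require_safe):
                    return True
        for p in positions(0):  # break the start codon itself
            if free(p, allow_committed):
                if _try_writes(builder, flip(p), require_safe):
                    return True
        for ci in range(1, n_codons):
            for p in positions(ci):
                if free(p, allow_committed):
                    if _try_writes(builder, flip(p), require_safe):
                        return True
    return False


# ---------------------------------------------------------------------------
# Panel simulation
# ---------------------------------------------------------------------------

@dataclass
class PanelConfig:
    """Panel of genomes diverged along a known tree: protein families
    evolved by per-site substitution (and optional short indels), gene
    orders rearranged by inversions/transpositions, genomes reassembled
    from back-translated genes."""

    n_genes: int = 24
    gene_length_aa: tuple[int, int] = (120, 250)
    subst_rate: float = 1.0  # per-site substitution prob per unit branch length
    indel_rate: float = 0.0  # expected indel events per unit branch length
    indel_length: tuple[int, int] = (1, 4)
    inversions_per_genome: int = 0
    transpositions_per_genome: int = 0
    spacer_nt: int = 50
    at_target: float = 61.0
    seed: int = 0


@dataclass
class PanelSim:
    taxa: list[str]
    gene_families: dict[str, dict[str, str]]  # gene -> taxon -> protein
    site_ids: dict[str, dict[str, list[int]]]  # homology truth for MSA tests
    orders: dict[str, tuple[int, ...]]  # taxon -> signed gene order
    records: list[GenomeRecord] = field(default_factory=list)
    tree_newick: str = ""


_AA = "ACDEFGHIKLMNPQRSTVWY"

_BACKTABLE: dict[str, list[str]] = {}
for codon, aa in CODON_TABLE.items():
    _BACKTABLE.setdefault(aa, []).append(codon)


def _mutate(seq, ids, bl, cfg: PanelConfig, rng, fresh):
    """One branch of evolution: per-site substitution with probability
    1−exp(−rate·bl), then Poisson indel events (tracked site ids)."""
    p = 1.0 - np.exp(-cfg.subst_rate * bl)
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < p:
            choices = [a for a in _AA if a != out[i]]
            out[i] = choices[rng.integers(0, len(choices))]
    oids = list(ids)
    n_events = rng.poisson(cfg.indel_rate * bl) if cfg.indel_rate > 0 else 0
    for _ in range(int(n_events)):
        if len(out) < 10:
            break
        ln = int(rng.integers(cfg.indel_length[0], cfg.indel_length[1] + 1))
        if rng.random() < 0.5 and len(out) > ln + 5:  # deletion
            at = int(rng.integers(0, len(out) - ln))
            del out[at : at + ln]
            del oids[at : at + ln]
        else:  # insertion of fresh residues
            at = int(rng.integers(0, len(out) + 1))
            ins = [_AA[rng.integers(0, 20)] for _ in range(ln)]
            out[at:at] = ins
            oids[at:at] = [next(fresh) for _ in range(ln)]
    return out, oids


def _rearrange(order: list[int], cfg: PanelConfig, rng) -> list[int]:
    order = list(order)
    n = len(order)
    for _ in range(cfg.inversions_per_genome):
        i, j = sorted(rng.choice(n, size=2, replace=False))
        order[i : j + 1] = [-x for x in reversed(order[i : j + 1])]
    for _ in range(cfg.transpositions_per_genome):
        i, j = sorted(rng.choice(n, size=2, replace=False))
        j += 1
        block = order[i:j]
        rest = order[:i] + order[j:]
        at = int(rng.integers(0, len(rest) + 1))
        order = rest[:at] + block + rest[at:]
    return order


def _backtranslate(protein: str, rng) -> str:
    codons = [
        _BACKTABLE[aa][rng.integers(0, len(_BACKTABLE[aa]))]
        if aa in _BACKTABLE
        else "AAC"
        for aa in protein
    ]
    stops = sorted(STOP_CODONS)
    return "ATG" + "".join(codons) + stops[rng.integers(0, len(stops))]


def simulate_panel(tree_newick: str, config: PanelConfig) -> PanelSim:
    """Evolve ``n_genes`` protein families and a signed gene order along
    the given tree (Newick, branch lengths required), then assemble one
    annotated genome per leaf.  Returns families, per-site homology
    truth, true gene-order vectors, and the genome records."""
    import dendropy

    tree = dendropy.Tree.get(data=tree_newick, schema="newick")
    rng = np.random.default_rng(config.seed)
    fresh = itertools.count(10**6)

    lo, hi = config.gene_length_aa
    root_genes = []
    for _ in range(config.n_genes):
        ln = int(rng.integers(lo, hi + 1))
        seq = [_AA[i] for i in rng.integers(0, 20, size=ln)]
        root_genes.append((seq, list(range(ln))))

    leaf_data: dict[str, list] = {}
    leaf_order: list[str] = []

    def walk(node, genes):
        for child in node.child_nodes():
            bl = child.edge.length if child.edge.length is not None else 0.0
            child_genes = [
                _mutate(seq, ids, bl, config, rng, fresh) for seq, ids in genes
            ]
            if child.is_leaf():
                name = child.taxon.label.replace(" ", "_")
                leaf_data[name] = child_genes
                leaf_order.append(name)
            else:
                walk(child, child_genes)

    walk(tree.seed_node, root_genes)
    if not leaf_data:
        raise InputError("tree has no leaves")

    gene_names = [f"g{k + 1:02d}" for k in range(config.n_genes)]
    families = {
        g: {t: "".join(leaf_data[t][k][0]) for t in leaf_order}
        for k, g in enumerate(gene_names)
    }
    site_ids = {
        g: {t: list(leaf_data[t][k][1]) for t in leaf_order}
        for k, g in enumerate(gene_names)
    }

    orders: dict[str, tuple[int, ...]] = {}
    for i, t in enumerate(leaf_order):
        base = list(range(1, config.n_genes + 1))
        # the first leaf is the anchored focal genome: identity order
        orders[t] = tuple(base if i == 0 else _rearrange(base, config, rng))

    bases, bprobs = _base_probs(config.at_target)
    records = []
    for t in leaf_order:
        parts: list[str] = []
        feats: list[OrfAnnotation] = []
        cursor = 1
        for signed in orders[t]:
            k = abs(signed) - 1
            spacer = "".join(rng.choice(bases, size=config.spacer_nt, p=bprobs))
            parts.append(spacer)
            cursor += len(spacer)
            nt = _backtranslate(families[gene_names[k]][t], rng)
            strand = 1 if signed > 0 else -1
            if strand == -1:
                parts.append(revcomp(nt))
                start = cursor + len(nt) - 1
            else:
                parts.append(nt)
                start = cursor
            feats.append(
                OrfAnnotation(
                    f"{t}_{gene_names[k]}",
                    start,
                    start + strand * (len(nt) - 1),
                    strand,
                    len(nt),
                    False,
                )
            )
            cursor += len(nt)
        tail = "".join(rng.choice(bases, size=config.spacer_nt, p=bprobs))
        parts.append(tail)
        records.append(GenomeRecord(t, "".join(parts), circular=True, features=feats))
    return PanelSim(
        taxa=leaf_order,
        gene_families=families,
        site_ids=site_ids,
        orders=orders,
        records=records,
        tree_newick=tree_newick,
    )
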
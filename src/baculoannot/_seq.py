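"""Low-level nucleotide helpers shared across modules.

All coordinates handled here are 0-based internal offsets; the public
dataclasses in :mod:`baculoannot.genome_io` expose 1-based inclusive
coordinates matching GenBank/GFF3 conventions.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

DNA_ALPHABET = set("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA
START_CODON = "ATG"

# codon -> aa for the standard code; codons with N fall through to "X"
CODON_TABLE = dict(standard_dna_table.forward_table)


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def translate_codons(cds: str) -> str:
    """Translate a coding sequence (standard code). Codons containing N or
    of incomplete length give X; stop codons give ``*``."""
    aa = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS:
            aa.append("*")
        else:
            aa.append(CODON_TABLE.get(codon, "X"))
    return "".join(aa)


def circular_slice(seq: str, start0: int, length: int) -> str:
    """Slice ``length`` characters starting at 0-based ``start0``, wrapping
    past the end (circular topology). ``length`` may not exceed len(seq)."""
    n = len(seq)
    if length > n:
        raise ValueError("slice longer than the (circular) sequence")
    start0 %= n
    end = start0 + length
    if end <= n:
        return seq[start0:end]
    return seq[start0:] + seq[: end - n]


def at_percent(seq: str) -> float:
    """A+T content in percent over the full sequence (N counted in the
    denominator), unrounded."""
    if not seq:
        return 0.0
    at = seq.count("A") + seq.count("T")
    return 100.0 * at / len(seq)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (the convention
    used for printed percentages; Python's round() is half-even)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
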
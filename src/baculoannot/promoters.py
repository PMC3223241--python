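"""Early/late promoter-motif association for baculovirus ORFs.

Baculovirus genes are conventionally classed by the transcription signal
found upstream of the start codon:

* **late** genes carry the (A/T/G)TAAG motif (``DTAAG`` in IUPAC
  notation), recognised by the viral RNA polymerase;
* **early** genes carry a host-type TATA box (``TATAA``) with a ``CAGT``
  initiator starting 20–40 nt downstream of the TATA-box start.

Both motif families are searched on the ORF's coding strand within a
configurable window (default 120 nt) immediately upstream of the start
codon, wrapping the origin on circular genomes.  Upstream regions that
overlap a neighbouring ORF are still scanned (no masking).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from ._seq import circular_slice, revcomp
from .errors import ConfigError
from .genome_io import GenomeRecord, OrfSet

WINDOW_DEFAULT = 120
LATE_MOTIF_DEFAULT = "DTAAG"
EARLY_TATA_DEFAULT = "TATAA"
EARLY_INR_DEFAULT = "CAGT"
EARLY_SPACING_DEFAULT = (20, 40)  # nt from TATA start to initiator start

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def iupac_to_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC nucleotide pattern to a regex (overlapping hits
    are found via lookahead)."""
    try:
        body = "".join(_IUPAC[c] for c in pattern.upper())
    except KeyError as exc:
        raise ConfigError(f"invalid IUPAC symbol {exc.args[0]!r} in motif {pattern!r}")
    if not pattern:
        raise ConfigError("empty motif pattern")
    return re.compile(f"(?=({body}))")


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    offset_upstream: int  # nt from the motif's first base to the base before ATG, +1
    sequence: str  # the matched bases, coding-strand orientation


@dataclass
class PromoterCall:
    orf_name: str
    promoter_class: str  # early | late | both | none
    motif_hits: list[MotifHit] = field(default_factory=list)


def upstream_window(record: GenomeRecord, orf, window_nt: int) -> str:
    """The ``window_nt`` bases immediately 5' of the ORF's start codon,
    read 5'→3' on the ORF's coding strand (the base adjacent to the ATG
    is the last character).  Truncated at the sequence ends on linear
    genomes."""
    L = len(record)
    w = min(window_nt, L - 1) if record.circular else window_nt
    if orf.strand == 1:
        if record.circular:
            return circular_slice(record.sequence, (orf.start - 1 - w) % L, w)
        lo = max(0, orf.start - 1 - w)
        return record.sequence[lo : orf.start - 1]
    if record.circular:
        return revcomp(circular_slice(record.sequence, orf.start % L, w))
    return revcomp(record.sequence[orf.start : orf.start + w])


def scan_promoters(
    record: GenomeRecord,
    orfset: OrfSet,
    window_nt: int = WINDOW_DEFAULT,
    late_motif: str = LATE_MOTIF_DEFAULT,
    early_tata: str = EARLY_TATA_DEFAULT,
    early_inr: str = EARLY_INR_DEFAULT,
    early_spacing: tuple[int, int] = EARLY_SPACING_DEFAULT,
) -> list[PromoterCall]:
    """Assign each ORF a promoter class from motif hits in its upstream
    window.  A late hit is any occurrence of ``late_motif``; an early hit
    is a ``early_tata`` occurrence with an ``early_inr`` occurrence
    starting ``early_spacing`` nt downstream of the TATA start (the
    initiator may run past the window edge into the ORF-proximal side)."""
    if window_nt < 1:
        raise ConfigError("window_nt must be ≥ 1")
    late_re = iupac_to_regex(late_motif)
    tata_re = iupac_to_regex(early_tata)
    inr_re = iupac_to_regex(early_inr)
    lo_sp, hi_sp = early_spacing

    calls: list[PromoterCall] = []
    for orf in orfset:
        win = upstream_window(record, orf, window_nt)
        W = len(win)
        hits: list[MotifHit] = []
        for m in late_re.finditer(win):
            i = m.start()
            hits.append(MotifHit("late", W - i, m.group(1)))
        inr_starts = [m.start() for m in inr_re.finditer(win)]
        for m in tata_re.finditer(win):
            i = m.start()
            if any(lo_sp <= j - i <= hi_sp for j in inr_starts):
                hits.append(MotifHit("early", W - i, m.group(1)))
        has_late = any(h.motif_id == "late" for h in hits)
        has_early = any(h.motif_id == "early" for h in hits)
        cls = (
            "both" if has_late and has_early
            else "late" if has_late
            else "early" if has_early
            else "none"
        )
        hits.sort(key=lambda h: (-h.offset_upstream, h.motif_id))
        calls.append(PromoterCall(orf.name, cls, hits))
    return calls


def load_motif_config(path) -> dict[str, str]:
    """Read a plain-text ``key=pattern`` motif file (one per line, ``#``
    comments allowed)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{ln}: expected key=pattern")
            k, v = (s.strip() for s in line.split("=", 1))
            iupac_to_regex(v)  # validate
            out[k] = v
    return out
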
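"""In-silico PCR: primer-site search and virtual amplification.

Locates binding sites of an oligonucleotide on a linear or circular template
(both strands, IUPAC-aware, with a mismatch budget) and extracts every
productive forward/reverse pairing as a predicted amplicon.  The Mito_F/R
pair targets the conserved tRNA-Ile ... tRNA-Met block of the tephritid
mitogenome; on *Bactrocera dorsalis* accession ON861824 the primers sit at
positions 12-36 and 203-227 (1-based inclusive), a 216 bp product.

Matching rule: a template base matches a primer base iff their IUPAC base
sets intersect.  Circular templates are scanned across the origin by sliding
over the doubled sequence and reporting starts modulo the template length.
Coordinates are 0-based half-open internally; an interval end beyond the
template length denotes an origin-spanning feature.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .seqs import encode_bits, gc_fraction_pct, reverse_complement, validate_alphabet

MITO_F_SEQ = "TGACAAAAGGGTTACCTTGATAGGG"
MITO_R_SEQ = "ACCCAGTAGCTTAATTAGCTTATCT"

#: 3' fidelity window: no mismatch tolerated in the last bases of the primer
THREE_PRIME_WINDOW = 5

DEFAULT_MAX_MISMATCH = 3
DEFAULT_MAX_PRODUCT_LEN = 2000


@dataclass(frozen=True)
class Primer:
    """A PCR oligo, 5'->3', optionally with its published annotation."""

    id: str
    sequence: str
    reported_location: Optional[tuple[int, int]] = None  # 1-based inclusive
    reported_tm: Optional[float] = None
    reported_gc: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("primer sequence must be non-empty")
        validate_alphabet(self.sequence, allow_degenerate=True)

    def __len__(self) -> int:
        return len(self.sequence)


MITO_F = Primer("Mito_F", MITO_F_SEQ, reported_location=(12, 36),
                reported_tm=56.6, reported_gc=44.0)
MITO_R = Primer("Mito_R", MITO_R_SEQ, reported_location=(203, 227),
                reported_tm=53.4, reported_gc=36.0)


@dataclass(frozen=True)
class PrimerHit:
    """One binding site. `start`/`end` are 0-based half-open on the plus
    strand of the (linearised) template; `end` may exceed the template
    length for origin-spanning sites on circular templates."""

    primer_id: str
    strand: str  # '+' or '-'
    start: int
    end: int
    mismatches: int
    three_prime_clean: bool


@dataclass
class AmpliconRecord:
    """A predicted product, 5'->3' on the forward-primer strand, primer
    footprints included."""

    sequence: str
    template_id: str
    template_interval: tuple[int, int]
    strand: str  # strand carrying the forward primer
    fwd_mismatches: int = 0
    rev_mismatches: int = 0
    multiple_products: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


class NoProductError(Exception):
    """No productive forward/reverse primer pairing on the template."""


def compute_gc(primer: Primer | str) -> float:
    """GC content in percent, rounded to 1 decimal (undefined for degenerate
    bases; raises naming the offending symbol)."""
    seq = primer.sequence if isinstance(primer, Primer) else primer
    return round(gc_fraction_pct(seq), 1)


def _scan_one_strand(template_bits: np.ndarray, probe_bits: np.ndarray) -> np.ndarray:
    """Mismatch count of the probe at every start position (vectorised)."""
    m = len(probe_bits)
    if len(template_bits) < m:
        return np.empty((0,), dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(template_bits, m)
    return ((windows & probe_bits[np.newaxis, :]) == 0).sum(axis=1)


def find_primer_sites(
    template: str,
    circular: bool,
    primer: Primer,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    require_three_prime_clean: bool = True,
) -> list[PrimerHit]:
    """All plus- and minus-strand binding sites with <= `max_mismatch`
    IUPAC-compatible mismatches, sorted by start then strand."""
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be non-negative")
    template = template.upper()
    validate_alphabet(template)
    n = len(template)
    m = len(primer)
    if n == 0 or (not circular and n < m):
        return []

    scan_seq = template + template[: m - 1] if circular else template
    bits = encode_bits(scan_seq)
    fwd_probe = encode_bits(primer.sequence.upper())
    # a minus-strand primer site at template window w satisfies: revcomp(w)
    # matches the primer, i.e. w matches revcomp(primer)
    rev_probe = encode_bits(reverse_complement(primer.sequence.upper()))

    hits: list[PrimerHit] = []
    for strand, probe in (("+", fwd_probe), ("-", rev_probe)):
        counts = _scan_one_strand(bits, probe)
        limit = n if circular else len(counts)
        for start in np.nonzero(counts <= max_mismatch)[0]:
            if start >= limit:
                continue
            window = bits[start:start + m]
            mism_idx = np.nonzero((window & probe) == 0)[0]
            # map window offsets to primer coordinates (5'->3')
            if strand == "+":
                primer_pos = mism_idx
            else:
                primer_pos = m - 1 - mism_idx
            clean = bool(np.all(primer_pos < m - THREE_PRIME_WINDOW)) if len(primer_pos) else True
            if require_three_prime_clean and not clean:
                continue
            hits.append(
                PrimerHit(
                    primer_id=primer.id,
                    strand=strand,
                    start=int(start),
                    end=int(start) + m,
                    mismatches=int(counts[start]),
                    three_prime_clean=clean,
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def _extract(template: str, circular: bool, start: int, end: int) -> str:
    n = len(template)
    if end <= n:
        return template[start:end]
    if not circular:
        raise ValueError("interval exceeds linear template")
    return (template + template)[start:end]


def virtual_pcr(
    template: str,
    circular: bool,
    fwd: Primer = MITO_F,
    rev: Primer = MITO_R,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    max_product_len: int = DEFAULT_MAX_PRODUCT_LEN,
    require_three_prime_clean: bool = True,
    template_id: str = "template",
) -> list[AmpliconRecord]:
    """Predict every product of the primer pair on the template.

    A product pairs a forward-primer site with an opposite-strand
    reverse-primer site downstream of it (in the forward primer's 3'
    direction), within `max_product_len`.  Multiple products are all
    returned and flagged; a template yielding none raises NoProductError.
    """
    if max_product_len <= 0:
        raise ValueError("max_product_len must be positive")
    template = template.upper()
    n = len(template)
    kwargs = dict(
        max_mismatch=max_mismatch,
        require_three_prime_clean=require_three_prime_clean,
    )
    fwd_hits = find_primer_sites(template, circular, fwd, **kwargs)
    rev_hits = find_primer_sites(template, circular, rev, **kwargs)

    products: list[AmpliconRecord] = []
    # orientation A: forward primer on '+', reverse primer on '-'
    for f in (h for h in fwd_hits if h.strand == "+"):
        for r in (h for h in rev_hits if h.strand == "-"):
            start, end = f.start, r.end
            if end <= f.end:
                if not circular:
                    continue
                end += n  # product wraps the origin
            if end - start < f.end - f.start + r.end - r.start:
                continue  # overlapping primer footprints are unproductive
            if end - start > max_product_len:
                continue
            products.append(
                AmpliconRecord(
                    sequence=_extract(template, circular, start, end),
                    template_id=template_id,
                    template_interval=(start, end),
                    strand="+",
                    fwd_mismatches=f.mismatches,
                    rev_mismatches=r.mismatches,
                )
            )
    # orientation B: forward primer on '-', reverse primer on '+'
    for f in (h for h in fwd_hits if h.strand == "-"):
        for r in (h for h in rev_hits if h.strand == "+"):
            start, end = r.start, f.end
            if end <= r.end:
                if not circular:
                    continue
                end += n
            if end - start < f.end - f.start + r.end - r.start:
                continue
            if end - start > max_product_len:
                continue
            products.append(
                AmpliconRecord(
                    sequence=reverse_complement(_extract(template, circular, start, end)),
                    template_id=template_id,
                    template_interval=(start, end),
                    strand="-",
                    fwd_mismatches=f.mismatches,
                    rev_mismatches=r.mismatches,
                )
            )

    if not products:
        raise NoProductError(
            f"no productive {fwd.id}/{rev.id} pairing on {template_id!r}"
        )
    if len(products) > 1:
        for p in products:
            p.multiple_products = True
    products.sort(key=lambda p: (p.template_interval, p.strand))
    return products
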
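"""Synthetic amplicons, spacers and toy circular mitogenomes.

The simulator reproduces the architecture of the Mito_F/R amplicon: a 56 bp
partial tRNA-Ile (beginning with the forward primer footprint), intergenic
region I, the complete 69 bp tRNA-Gln, intergenic region II, and a 29 bp
partial tRNA-Met ending in the reverse-primer footprint.  Spacer lengths are
drawn from the published species windows (IGS-I: 40/2/62-64/34/0 bp; IGS-II:
16-18 bp for *C. quilicii*, 18-22 bp for *C. rosa*).  Species without a
published IGS-II length get simulator-only defaults (see SYNTHETIC_IGS2_LEN;
the 62 bp *B. dorsalis* value is forced by the primers' published positions,
which imply a 216 bp product).  Base composition is AT-rich to match the
assembled mitogenomes (73.6-77.4% AT).

The tRNA segments are fixed per-genus stand-in constants, not the real gene
sequences (which are not reproduced here); one set per genus, >= 85%
mutually identical, mirroring tRNA conservation.  Real-data runs take their
tRNA references from the input annotation instead.  Within a species the
spacer *sequence* is a fixed canonical constant truncated to the drawn
length, so intraspecific variation comes from length draws and optional
noise only -- matching the reported within-species consistency.

All randomness flows from one integer seed: each operation derives an
independent stream via ``numpy.random.SeedSequence([seed, stream_id])``
with a fixed per-operation stream id.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .pcr import MITO_F, MITO_R, find_primer_sites
from .seqs import reverse_complement
from .signatures import (
    DEFAULT_SPECIES,
    SPECIES_CAPITATA,
    SPECIES_COSYRA,
    SPECIES_DORSALIS,
    SPECIES_QUILICII,
    SPECIES_ROSA,
    build_default_table,
)

# ---------------------------------------------------------------------------
# frozen stand-in constants (generated once, AT-rich, primer footprints at the
# amplicon termini; Bactrocera differs from Ceratitis at ~10% of positions)
# ---------------------------------------------------------------------------

TRNA_ILE_CERATITIS = "TGACAAAAGGGTTACCTTGATAGGGACCTGCTCGTCATTTGACAATTCTGGAATAG"
TRNA_GLN_CERATITIS = "TGCTATGAATTGACTTTTTCTTCAAGACTACTAAAGAATAATAAATTTCAACATGTATGATAAGGTTTT"
TRNA_MET_CERATITIS = "AGAAAGATAAGCTAATTAAGCTACTGGGT"
TRNA_ILE_BACTROCERA = "TGACAAAAGGGTTACCTTGATAGGGACCATCTCGTCATTTGACACTTATGGAACAG"
TRNA_GLN_BACTROCERA = "TGCCATGCATTGACTTTTGCTTCAGGACTATGAAAGAATAATAAAATTCAACACGTATGATAAGGTTTT"
TRNA_MET_BACTROCERA = "ACGAAGATAAGCTAATTAAGCTACTGGGT"

ILE_SEGMENT_LEN = 56
GLN_SEGMENT_LEN = 69
MET_SEGMENT_LEN = 29
ANCHOR_TOTAL_LEN = ILE_SEGMENT_LEN + GLN_SEGMENT_LEN + MET_SEGMENT_LEN

#: canonical per-species spacer sequences (prefix-truncated to drawn length)
CANONICAL_IGS1 = {
    SPECIES_CAPITATA: "TTCTACATTCAAATTCAAAATATAAACTATTTATCGCTAT",
    SPECIES_COSYRA: "AT",
    SPECIES_QUILICII: "TCTAACTTACTTATGTATAATAGTTAAATGGAACACCATTGCAAAATACATAATTTACTAAACT",
    SPECIES_ROSA: "TAAACTATTTTTATCGTATATTATAGAGAATCAT",
    SPECIES_DORSALIS: "",
}
CANONICAL_IGS2 = {
    SPECIES_CAPITATA: "CCTTAATTGTATTCTAATT",
    SPECIES_COSYRA: "TAAAAAATTAAATTAGAAG",
    SPECIES_QUILICII: "TCTCATTTTCCAGTTATA",
    SPECIES_ROSA: "GATAACGCATTTAAAAAAGTTA",
    SPECIES_DORSALIS: "AGGCTTTATAATGTGGGTTATAATTATGTGAGTTAAAGATTCGTTTATCCTTCTAATATTAA",
}

#: simulator-only IGS-II length windows for species without printed values
SYNTHETIC_IGS2_LEN = {
    SPECIES_CAPITATA: (19, 19),
    SPECIES_COSYRA: (19, 19),
    SPECIES_DORSALIS: (62, 62),
}

#: whole-mitogenome AT fractions of the study accessions
GENOME_AT_FRACTION = {
    SPECIES_CAPITATA: 0.774,
    SPECIES_COSYRA: 0.762,
    SPECIES_QUILICII: 0.772,
    SPECIES_ROSA: 0.773,
    SPECIES_DORSALIS: 0.736,
}

DEFAULT_AT_FRACTION = 0.77

# stream ids for the seed-splitting rule
_STREAM_SPACER = 1
_STREAM_AMPLICON = 2
_STREAM_GENOME = 3
_STREAM_NOISE = 4

_GENUS_TRNAS = {
    "Ceratitis": (TRNA_ILE_CERATITIS, TRNA_GLN_CERATITIS, TRNA_MET_CERATITIS),
    "Bactrocera": (TRNA_ILE_BACTROCERA, TRNA_GLN_BACTROCERA, TRNA_MET_BACTROCERA),
}


def trna_segments(species: str) -> tuple[str, str, str]:
    """(ile, gln, met) stand-in segments for the species' genus."""
    genus = species.split()[0].capitalize()
    try:
        return _GENUS_TRNAS[genus]
    except KeyError:
        raise KeyError(f"no stand-in tRNA set for genus {genus!r}") from None


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


@dataclass(frozen=True)
class NoiseModel:
    """Per-base substitution/insertion/deletion rates (Sanger-style errors)."""

    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            r = getattr(self, name)
            if not 0 <= r < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.sub_rate + self.ins_rate + self.del_rate >= 1:
            raise ValueError("rates must sum to < 1")


@dataclass(frozen=True)
class Edit:
    """One recorded change: op in {'sub','ins','del'}, position on the
    original sequence, original base ('' for ins), new base ('' for del)."""

    op: str
    pos: int
    orig: str
    new: str


@dataclass
class SyntheticAmplicon:
    sequence: str
    truth_species: str
    truth_igs1: str
    truth_igs2: str
    truth_anchors: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass
class SyntheticGenome:
    sequence: str
    rotation: int
    truth_amplicon_interval: tuple[int, int]  # on the unrotated forward strand
    truth_species: str

    @property
    def unrotated(self) -> str:
        n = len(self.sequence)
        r = self.rotation % n
        return self.sequence[n - r:] + self.sequence[: n - r]


def make_spacer(length: int, at_fraction: float = DEFAULT_AT_FRACTION,
                rng_seed: int | np.random.Generator = 0) -> str:
    """Random spacer: bases i.i.d., A/T each at_fraction/2, C/G otherwise."""
    if length < 0:
        raise ValueError("length must be non-negative")
    if not 0 <= at_fraction <= 1:
        raise ValueError("at_fraction must be in [0, 1]")
    if length == 0:
        return ""
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else _rng(rng_seed, _STREAM_SPACER))
    p = [at_fraction / 2, (1 - at_fraction) / 2, (1 - at_fraction) / 2, at_fraction / 2]
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=p))


def _species_spacer(species: str, canonical: str, length: int,
                    rng: np.random.Generator) -> str:
    """Canonical spacer truncated/extended to `length`."""
    if length <= len(canonical):
        return canonical[:length]
    return canonical + make_spacer(length - len(canonical), DEFAULT_AT_FRACTION, rng)


def make_amplicon(
    species: str,
    rng_seed: int = 0,
    igs1_len_override: Optional[int] = None,
    igs2_len_override: Optional[int] = None,
) -> SyntheticAmplicon:
    """Simulate one error-free amplicon for a species in the default table."""
    table = build_default_table()
    if species not in table.species():
        raise KeyError(f"unknown species {species!r}")
    rng = _rng(rng_seed, _STREAM_AMPLICON)
    lo1, hi1 = table.igs1_window(species)
    igs1_len = int(rng.integers(lo1, hi1 + 1)) if igs1_len_override is None else igs1_len_override
    try:
        lo2, hi2 = table.igs2_window(species)
    except KeyError:
        lo2, hi2 = SYNTHETIC_IGS2_LEN[species]
    igs2_len = int(rng.integers(lo2, hi2 + 1)) if igs2_len_override is None else igs2_len_override
    if igs1_len < 0 or igs2_len < 0:
        raise ValueError("spacer length overrides must be non-negative")

    ile, gln, met = trna_segments(species)
    igs1 = _species_spacer(species, CANONICAL_IGS1[species], igs1_len, rng)
    igs2 = _species_spacer(species, CANONICAL_IGS2[species], igs2_len, rng)
    seq = ile + igs1 + gln + igs2 + met
    a = len(ile)
    b = a + len(igs1)
    c = b + len(gln)
    d = c + len(igs2)
    return SyntheticAmplicon(
        sequence=seq,
        truth_species=species,
        truth_igs1=igs1,
        truth_igs2=igs2,
        truth_anchors=((0, a), (b, c), (d, d + len(met))),
    )


def make_genome(
    species: str,
    total_length: int = 16000,
    rng_seed: int = 0,
    at_fraction: Optional[float] = None,
    max_mismatch: int = 3,
) -> SyntheticGenome:
    """Toy circular mitogenome: the species amplicon (intact primer sites)
    embedded in AT-rich filler free of secondary primer sites, at a seeded
    random rotation."""
    amplicon = make_amplicon(species, rng_seed=rng_seed)
    amp = amplicon.sequence
    if total_length < len(amp) + 200:
        raise ValueError(
            f"total_length must be >= amplicon length + 200 ({len(amp) + 200})"
        )
    at = GENOME_AT_FRACTION[species] if at_fraction is None else at_fraction
    rng = _rng(rng_seed, _STREAM_GENOME)
    for _ in range(50):
        filler = make_spacer(total_length - len(amp), at, rng)
        circ = amp + filler
        f_hits = find_primer_sites(circ, True, MITO_F, max_mismatch,
                                   require_three_prime_clean=False)
        r_hits = find_primer_sites(circ, True, MITO_R, max_mismatch,
                                   require_three_prime_clean=False)
        expected_f = [(h.strand, h.start) for h in f_hits] == [("+", 0)]
        expected_r = [(h.strand, h.start) for h in r_hits] == [("-", len(amp) - len(MITO_R))]
        if expected_f and expected_r:
            rotation = int(rng.integers(total_length))
            seq = circ[rotation:] + circ[:rotation]
            return SyntheticGenome(
                sequence=seq,
                rotation=rotation,
                truth_amplicon_interval=(0, len(amp)),
                truth_species=species,
            )
    raise RuntimeError("could not generate filler free of secondary primer sites")


def apply_noise(sequence: str, model: NoiseModel) -> tuple[str, list[Edit]]:
    """Apply per-base substitution/insertion/deletion noise.

    For each original base, deletion is drawn first, then substitution;
    independently an insertion may be placed after the base.  The edit log
    records every change against original coordinates; with all rates zero
    the sequence is returned unchanged with an empty log.
    """
    rng = _rng(model.seed, _STREAM_NOISE)
    bases = "ACGT"
    out: list[str] = []
    log: list[Edit] = []
    n = len(sequence)
    if n == 0:
        return "", []
    u = rng.random((n, 3))
    for i, base in enumerate(sequence):
        if u[i, 0] < model.del_rate:
            log.append(Edit("del", i, base, ""))
        else:
            if u[i, 1] < model.sub_rate:
                new = bases[(bases.index(base) + 1 + int(rng.integers(3))) % 4] \
                    if base in bases else "A"
                log.append(Edit("sub", i, base, new))
                out.append(new)
            else:
                out.append(base)
        if u[i, 2] < model.ins_rate:
            ins = bases[int(rng.integers(4))]
            log.append(Edit("ins", i, "", ins))
            out.append(ins)
    return "".join(out), log
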
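"""Amplicon dissection: tRNA anchor alignment and intergenic-spacer extraction.

The Mito_F/R amplicon is ile(56) + IGS-I + gln(69) + IGS-II + met(29).  The
three tRNA segments are conserved landmarks ("tRNA punctuation"); locating
them delimits the two variable spacers exactly.  Anchoring uses semi-global
pairwise alignment: the ile reference is pinned to the amplicon 5' end, the
met reference to the 3' end, and gln is aligned with free end gaps inside
the remaining interior, which removes placement ambiguity when a spacer is
short or absent.  An anchor whose alignment identity falls below
``min_identity`` (default 0.80) fails rather than mis-anchoring.

Scoring: match +1, mismatch -1, gap open -2, gap extend -1.  Identity is
matches / alignment columns over the span covering the reference, counting
gap columns (and any trimmed reference bases) in the denominator.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import islice
from typing import Union

from Bio import Align

from .pcr import AmpliconRecord
from .synthetic import (
    GLN_SEGMENT_LEN,
    ILE_SEGMENT_LEN,
    MET_SEGMENT_LEN,
    trna_segments,
)

MIN_AMPLICON_LEN = ILE_SEGMENT_LEN + GLN_SEGMENT_LEN + MET_SEGMENT_LEN

_PIN = -1e6  # effectively forbids an end gap


@dataclass(frozen=True)
class AlignmentParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    min_identity: float = 0.80


DEFAULT_PARAMS = AlignmentParams()


@dataclass(frozen=True)
class TrnaReferenceSet:
    """The three anchor references (amplicon-internal portions)."""

    ile: str
    gln: str
    met: str
    source: str = "synthetic stand-in"

    @classmethod
    def for_species(cls, species: str) -> "TrnaReferenceSet":
        ile, gln, met = trna_segments(species)
        return cls(ile=ile, gln=gln, met=met,
                   source=f"synthetic stand-in ({species.split()[0]})")


@dataclass
class AnchorSet:
    """Anchor intervals (0-based half-open, amplicon coordinates) and scores."""

    ile_interval: tuple[int, int]
    gln_interval: tuple[int, int]
    met_interval: tuple[int, int]
    scores: dict[str, tuple[float, float]]  # anchor -> (score, identity)

    @property
    def total_score(self) -> float:
        return sum(s for s, _ in self.scores.values())


@dataclass
class IgsPair:
    igs1_seq: str
    igs2_seq: str

    @property
    def igs1_len(self) -> int:
        return len(self.igs1_seq)

    @property
    def igs2_len(self) -> int:
        return len(self.igs2_seq)


class AnchorFailure(Exception):
    def __init__(self, anchor: str, identity: float):
        self.anchor = anchor
        self.identity = identity
        super().__init__(f"{anchor} anchor identity {identity:.3f} below threshold")


class OrderViolation(Exception):
    pass


def _aligner(params: AlignmentParams, free_left: bool, free_right: bool) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = params.match
    a.mismatch_score = params.mismatch
    a.open_gap_score = params.gap_open
    a.extend_gap_score = params.gap_extend
    # "deletion" = gap in the query row, i.e. skipped target bases; freeing
    # the end deletions makes the alignment semi-global in the target
    a.open_left_deletion_score = 0.0 if free_left else _PIN
    a.extend_left_deletion_score = 0.0 if free_left else _PIN
    a.open_right_deletion_score = 0.0 if free_right else _PIN
    a.extend_right_deletion_score = 0.0 if free_right else _PIN
    return a


def _stats(alignment, query_len: int) -> tuple[int, int, int, int]:
    """(target_start, target_end, matches, columns) over the reference span."""
    tblocks, qblocks = alignment.aligned
    if len(tblocks) == 0:
        return 0, 0, 0, max(query_len, 1)
    target = str(alignment.target)
    query = str(alignment.query)
    matches = 0
    block_total = 0
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        block_total += te - ts
        matches += sum(a == b for a, b in zip(target[ts:te], query[qs:qe]))
    t_start, t_end = int(tblocks[0][0]), int(tblocks[-1][1])
    q_start, q_end = int(qblocks[0][0]), int(qblocks[-1][1])
    columns = (t_end - t_start) + (q_end - q_start) - block_total
    columns += q_start + (query_len - q_end)  # trimmed reference bases count
    return t_start, t_end, matches, columns


def _align_anchor(target: str, ref: str, aligner: Align.PairwiseAligner,
                  name: str, min_identity: float) -> tuple[int, int, float, float]:
    alignments = aligner.align(target, ref)

    # Equal-score placements are resolved by preferring the indel-free span
    # (target span == reference length; substitutions alone never shift a
    # boundary) and then the leftmost start.  Bounded enumeration: optimal
    # ties beyond the cap are vanishingly rare for these anchor lengths.
    def tie_key(aln):
        t_start, t_end, _, _ = _stats(aln, len(ref))
        return (abs((t_end - t_start) - len(ref)), t_start)

    best = min(islice(alignments, 32), key=tie_key)
    t_start, t_end, matches, columns = _stats(best, len(ref))
    identity = matches / columns if columns else 0.0
    if identity < min_identity:
        raise AnchorFailure(name, identity)
    return t_start, t_end, float(best.score), identity


def anchor_trnas(
    amplicon: Union[AmpliconRecord, str],
    refs: TrnaReferenceSet,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> AnchorSet:
    """Locate the three tRNA anchors inside an amplicon.

    Raises AnchorFailure when an anchor cannot be placed at the required
    identity, OrderViolation when the placements overlap or misorder.
    """
    seq = amplicon.sequence if isinstance(amplicon, AmpliconRecord) else amplicon
    seq = seq.upper()
    if len(seq) < MIN_AMPLICON_LEN:
        raise ValueError(
            f"amplicon length {len(seq)} below minimum {MIN_AMPLICON_LEN}"
        )
    # ile pinned to the 5' end
    _, ile_end, ile_score, ile_ident = _align_anchor(
        seq, refs.ile, _aligner(params, free_left=False, free_right=True),
        "ile", params.min_identity,
    )
    # met pinned to the 3' end
    met_start, _, met_score, met_ident = _align_anchor(
        seq, refs.met, _aligner(params, free_left=True, free_right=False),
        "met", params.min_identity,
    )
    if met_start < ile_end:
        raise OrderViolation("ile and met anchor placements overlap")
    # gln free at both ends within the interior window
    interior = seq[ile_end:met_start]
    g_start, g_end, gln_score, gln_ident = _align_anchor(
        interior, refs.gln, _aligner(params, free_left=True, free_right=True),
        "gln", params.min_identity,
    )
    gln_interval = (ile_end + g_start, ile_end + g_end)
    return AnchorSet(
        ile_interval=(0, ile_end),
        gln_interval=gln_interval,
        met_interval=(met_start, len(seq)),
        scores={
            "ile": (ile_score, ile_ident),
            "gln": (gln_score, gln_ident),
            "met": (met_score, met_ident),
        },
    )


def extract_igs(amplicon: Union[AmpliconRecord, str], anchors: AnchorSet) -> IgsPair:
    """Cut out the two spacers delimited by the anchors."""
    seq = amplicon.sequence if isinstance(amplicon, AmpliconRecord) else amplicon
    seq = seq.upper()
    if not (0 <= anchors.ile_interval[1] <= anchors.gln_interval[0]
            <= anchors.gln_interval[1] <= anchors.met_interval[0] <= len(seq)):
        raise OrderViolation("anchor intervals misordered for this amplicon")
    return IgsPair(
        igs1_seq=seq[anchors.ile_interval[1]:anchors.gln_interval[0]],
        igs2_seq=seq[anchors.gln_interval[1]:anchors.met_interval[0]],
    )


def dissect(
    amplicon: Union[AmpliconRecord, str],
    refs: TrnaReferenceSet,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> tuple[AnchorSet, IgsPair]:
    """anchor_trnas + extract_igs in one call."""
    anchors = anchor_trnas(amplicon, refs, params)
    return anchors, extract_igs(amplicon, anchors)
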
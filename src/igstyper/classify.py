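"""Species calling from dissected amplicons.

Primary evidence is the IGS-I length signature: a measured length matching
exactly one tolerance-expanded species window yields an unambiguous call.
IGS-II may corroborate or contradict a call but never establishes one on its
own (its windows overlap for *C. rosa* and *C. quilicii*); a contradiction
downgrades the call to ambiguous.  When the length gives no call (or
anchoring fails) and a reference panel is available, a nearest-neighbour
percent-identity fallback is used: unambiguous iff the best reference is
close enough (>= ``min_identity_pct``) and clearly separated from the
runner-up (margin >= ``min_margin``).  Confounding taxa reported for the
called species are attached as caveats, never used to reject a call.

Orientation is auto-detected: anchoring runs on both strands and the higher
total anchor score wins, so a reverse-complemented read classifies
identically.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from Bio import Align

from .dissect import (
    DEFAULT_PARAMS,
    AlignmentParams,
    AnchorFailure,
    AnchorSet,
    IgsPair,
    OrderViolation,
    TrnaReferenceSet,
    anchor_trnas,
    extract_igs,
)
from .pcr import AmpliconRecord
from .seqs import reverse_complement
from .signatures import SignatureTable, build_default_table

STATUS_UNAMBIGUOUS = "unambiguous"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_NO_CALL = "no_call"

#: identity fallback acceptance thresholds (percent / percentage points)
DEFAULT_MIN_MARGIN = 2.0
DEFAULT_MIN_IDENTITY_PCT = 90.0


@dataclass
class IdentityCall:
    best_species: str
    best_identity: float
    runner_up: Optional[str]
    margin: float


@dataclass
class SpeciesCall:
    status: str
    species: Optional[str] = None
    candidates: tuple[str, ...] = ()
    evidence: dict = field(default_factory=dict)
    identity_evidence: Optional[IdentityCall] = None
    caveats: tuple[tuple[str, float], ...] = ()
    notes: tuple[str, ...] = ()


def call_by_length(igs1_len: int, table: Optional[SignatureTable] = None) -> SpeciesCall:
    """Species call from the IGS-I length alone (pure function of inputs)."""
    table = table or build_default_table()
    matches = table.match_igs1(igs1_len)
    evidence = {"igs1_len": igs1_len, "tolerance": table.tolerance}
    if len(matches) == 1:
        species = matches[0]
        evidence["matched_window"] = table.igs1_window(species)
        return SpeciesCall(
            status=STATUS_UNAMBIGUOUS,
            species=species,
            candidates=(species,),
            evidence=evidence,
            caveats=table.confounders(species),
        )
    if not matches:
        return SpeciesCall(status=STATUS_NO_CALL, evidence=evidence)
    return SpeciesCall(
        status=STATUS_AMBIGUOUS, candidates=tuple(matches), evidence=evidence
    )


def call_by_igs2_length(igs2_len: int, table: Optional[SignatureTable] = None) -> SpeciesCall:
    """Corroborating call from the IGS-II length; never unambiguous on its
    own, because the *C. rosa* / *C. quilicii* windows overlap."""
    table = table or build_default_table()
    matches = table.match_igs2(igs2_len)
    evidence = {"igs2_len": igs2_len, "tolerance": table.tolerance}
    if not matches:
        return SpeciesCall(status=STATUS_NO_CALL, evidence=evidence)
    notes = ("IGS-II length evidence is weak: corroborating only, never "
             "diagnostic on its own",)
    return SpeciesCall(
        status=STATUS_AMBIGUOUS,
        candidates=tuple(matches),
        evidence=evidence,
        notes=notes,
    )


def percent_identity(a: str, b: str, params: AlignmentParams = DEFAULT_PARAMS) -> float:
    """Global-alignment identity in percent; gap columns count in the
    denominator."""
    if not a or not b:
        raise ValueError("percent_identity requires two non-empty sequences")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    alignment = aligner.align(a.upper(), b.upper())[0]
    counts = alignment.counts()
    columns = alignment.length
    return 100.0 * counts.identities / columns if columns else 0.0


@dataclass
class ReferencePanel:
    """Named reference amplicons for the identity fallback (one per species
    is the default panel)."""

    entries: list[tuple[str, str]]  # (species, amplicon sequence)

    @classmethod
    def default_synthetic(cls, seed: int = 0) -> "ReferencePanel":
        from .synthetic import make_amplicon

        table = build_default_table()
        return cls(entries=[
            (sp, make_amplicon(sp, rng_seed=seed).sequence) for sp in table.species()
        ])


def _identity_fallback(
    seq: str,
    panel: ReferencePanel,
    params: AlignmentParams,
    min_margin: float,
    min_identity_pct: float,
    table: SignatureTable,
) -> SpeciesCall:
    scored: list[tuple[float, str]] = []
    rc = reverse_complement(seq)
    for species, ref in panel.entries:
        ident = max(percent_identity(seq, ref, params),
                    percent_identity(rc, ref, params))
        scored.append((ident, species))
    scored.sort(reverse=True)
    best_ident, best_species = scored[0]
    runner_ident, runner_species = scored[1] if len(scored) > 1 else (0.0, None)
    call = IdentityCall(
        best_species=best_species,
        best_identity=round(best_ident, 2),
        runner_up=runner_species,
        margin=round(best_ident - runner_ident, 2),
    )
    if best_ident < min_identity_pct:
        return SpeciesCall(
            status=STATUS_NO_CALL,
            identity_evidence=call,
            notes=("best panel identity below acceptance threshold",),
        )
    if call.margin < min_margin:
        return SpeciesCall(
            status=STATUS_AMBIGUOUS,
            candidates=(best_species, runner_species),
            identity_evidence=call,
            notes=("nearest-neighbour margin below acceptance threshold",),
        )
    return SpeciesCall(
        status=STATUS_UNAMBIGUOUS,
        species=best_species,
        candidates=(best_species,),
        identity_evidence=call,
        caveats=table.confounders(best_species),
        notes=("called by identity fallback",),
    )


def classify(
    amplicon: Union[AmpliconRecord, str],
    refs: TrnaReferenceSet,
    table: Optional[SignatureTable] = None,
    panel: Optional[ReferencePanel] = None,
    params: AlignmentParams = DEFAULT_PARAMS,
    min_margin: float = DEFAULT_MIN_MARGIN,
    min_identity_pct: float = DEFAULT_MIN_IDENTITY_PCT,
) -> SpeciesCall:
    """Full pipeline: orient, anchor, extract spacers, call by IGS-I length,
    corroborate with IGS-II, fall back to panel identity when needed."""
    table = table or build_default_table()
    seq = (amplicon.sequence if isinstance(amplicon, AmpliconRecord) else amplicon).upper()

    anchors: Optional[AnchorSet] = None
    oriented = seq
    failure: Optional[Exception] = None
    best_score = float("-inf")
    for candidate in (seq, reverse_complement(seq)):
        try:
            result = anchor_trnas(candidate, refs, params)
        except (AnchorFailure, OrderViolation, ValueError) as exc:
            failure = failure or exc
            continue
        if result.total_score > best_score:
            best_score = result.total_score
            anchors, oriented = result, candidate

    if anchors is None:
        if panel is not None:
            return _identity_fallback(seq, panel, params, min_margin,
                                      min_identity_pct, table)
        raise failure  # propagate the dissection error

    igs = extract_igs(oriented, anchors)
    call = call_by_length(igs.igs1_len, table)
    call.evidence.update(
        igs2_len=igs.igs2_len,
        anchor_identities={k: round(v[1], 3) for k, v in anchors.scores.items()},
        orientation="+" if oriented == seq else "-",
    )

    if call.status == STATUS_UNAMBIGUOUS:
        call = _corroborate_with_igs2(call, igs, table)
    if call.status == STATUS_NO_CALL and panel is not None:
        fallback = _identity_fallback(oriented, panel, params, min_margin,
                                      min_identity_pct, table)
        fallback.evidence = dict(call.evidence, **fallback.evidence)
        return fallback
    return call


def _corroborate_with_igs2(call: SpeciesCall, igs: IgsPair,
                           table: SignatureTable) -> SpeciesCall:
    """IGS-II cross-check for species with a published IGS-II window."""
    species = call.species
    try:
        table.igs2_window(species)
    except KeyError:
        return call  # no published window: IGS-II carries no information
    matches = table.match_igs2(igs.igs2_len)
    if species in matches:
        call.notes = call.notes + ("IGS-II length corroborates the call",)
        return call
    if matches:
        # measured IGS-II points at a different species: downgrade
        candidates = tuple(dict.fromkeys((species, *matches)))
        return SpeciesCall(
            status=STATUS_AMBIGUOUS,
            candidates=candidates,
            evidence=call.evidence,
            notes=call.notes + (
                "IGS-II length contradicts the IGS-I call; downgraded",
            ),
        )
    call.notes = call.notes + ("IGS-II length outside all published windows",)
    return call
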
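"""Species signature tables: diagnostic intergenic-spacer length windows.

The five tephritid pest species of South African fruit export can be told
apart by the length of mitochondrial intergenic region I (between tRNA-Ile
and tRNA-Gln): *Ceratitis capitata* 40 bp, *C. cosyra* 2 bp, *C. quilicii*
62-64 bp, *C. rosa* 34 bp and *Bactrocera dorsalis* 0 bp (the spacer is
absent in *Bactrocera*).  Intergenic region II (tRNA-Gln to tRNA-Met) is
16-18 bp in *C. quilicii* and 18-22 bp in *C. rosa*; the windows overlap, so
region II can corroborate but never separate that species pair.

Window matching applies a symmetric tolerance with one refinement: a 0 bp
spacer is the qualitative *absence* of the region, so absence windows do not
expand, and positive windows never expand below 2 bp -- a single observed
base between the anchors is within one sequencing error of absence and is
never treated as length-diagnostic.  Under the default 1 bp tolerance the
five region-I windows are pairwise disjoint.

Confounding taxa reported for whole-amplicon similarity searches against
GenBank (e.g. *C. fasciventris* at 100% for *C. quilicii*) are carried as
caveat metadata on calls; they never veto a call.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

SPECIES_CAPITATA = "Ceratitis capitata"
SPECIES_COSYRA = "Ceratitis cosyra"
SPECIES_QUILICII = "Ceratitis quilicii"
SPECIES_ROSA = "Ceratitis rosa"
SPECIES_DORSALIS = "Bactrocera dorsalis"

DEFAULT_SPECIES = (
    SPECIES_CAPITATA,
    SPECIES_COSYRA,
    SPECIES_QUILICII,
    SPECIES_ROSA,
    SPECIES_DORSALIS,
)


@dataclass(frozen=True)
class LengthWindow:
    """Closed integer window of spacer lengths in bp.

    Construction is permissive; `validate_table` reports invariant breaches
    (min > max, negative bounds) as data rather than raising.
    """

    min_len: int
    max_len: int

    def expand(self, tolerance: int) -> "LengthWindow":
        """Tolerance-expanded matching window.

        Absence windows (max_len == 0) are exact; positive windows expand
        symmetrically but never below 2 bp (see module docstring).
        """
        if tolerance < 0:
            raise ValueError("tolerance must be non-negative")
        if self.max_len == 0:
            return self
        lo = max(self.min_len - tolerance, min(self.min_len, 2))
        return LengthWindow(lo, self.max_len + tolerance)

    def contains(self, length: int) -> bool:
        return self.min_len <= length <= self.max_len

    def overlaps(self, other: "LengthWindow") -> bool:
        return self.min_len <= other.max_len and other.min_len <= self.max_len

    def as_tuple(self) -> tuple[int, int]:
        return (self.min_len, self.max_len)


@dataclass(frozen=True)
class SpeciesSignature:
    """One species' diagnostic windows plus reported confounding taxa."""

    species: str
    igs1_window: LengthWindow
    igs2_window: Optional[LengthWindow] = None
    confounders: tuple[tuple[str, float], ...] = ()


@dataclass
class SignatureTable:
    """A set of species signatures with a shared matching tolerance (bp)."""

    entries: list[SpeciesSignature]
    tolerance: int = 1

    def _find(self, species: str) -> SpeciesSignature:
        key = species.strip().lower()
        for entry in self.entries:
            if entry.species.lower() == key:
                return entry
        raise KeyError(f"unknown species {species!r}")

    def species(self) -> list[str]:
        return [e.species for e in self.entries]

    def igs1_window(self, species: str) -> tuple[int, int]:
        return self._find(species).igs1_window.as_tuple()

    def igs2_window(self, species: str) -> tuple[int, int]:
        window = self._find(species).igs2_window
        if window is None:
            raise KeyError(f"no printed IGS-II window for {species!r}")
        return window.as_tuple()

    def confounders(self, species: str) -> tuple[tuple[str, float], ...]:
        return self._find(species).confounders

    def match_igs1(self, length: int) -> list[str]:
        """Species whose tolerance-expanded IGS-I window contains `length`."""
        if length < 0:
            raise ValueError("length must be non-negative")
        return [
            e.species
            for e in self.entries
            if e.igs1_window.expand(self.tolerance).contains(length)
        ]

    def match_igs2(self, length: int) -> list[str]:
        """Species whose tolerance-expanded IGS-II window contains `length`."""
        if length < 0:
            raise ValueError("length must be non-negative")
        return [
            e.species
            for e in self.entries
            if e.igs2_window is not None
            and e.igs2_window.expand(self.tolerance).contains(length)
        ]

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "tolerance": self.tolerance,
            "entries": [
                {
                    "species": e.species,
                    "igs1_window": list(e.igs1_window.as_tuple()),
                    "igs2_window": (
                        list(e.igs2_window.as_tuple()) if e.igs2_window else None
                    ),
                    "confounders": [[t, p] for t, p in e.confounders],
                }
                for e in self.entries
            ],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, payload: dict) -> "SignatureTable":
        entries = []
        for raw in payload["entries"]:
            igs2 = raw.get("igs2_window")
            entries.append(
                SpeciesSignature(
                    species=raw["species"],
                    igs1_window=LengthWindow(*raw["igs1_window"]),
                    igs2_window=LengthWindow(*igs2) if igs2 else None,
                    confounders=tuple((t, float(p)) for t, p in raw.get("confounders", [])),
                )
            )
        return cls(entries=entries, tolerance=int(payload.get("tolerance", 1)))

    @classmethod
    def from_json(cls, source: str | Path) -> "SignatureTable":
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        return cls.from_dict(json.loads(text))

    def sha256(self) -> str:
        """Stable digest of the table content, echoed in every report."""
        canonical = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canonical.encode()).hexdigest()


def build_default_table(tolerance: int = 1) -> SignatureTable:
    """The five-species reference table with the published length signatures."""
    entries = [
        SpeciesSignature(SPECIES_CAPITATA, LengthWindow(40, 40)),
        SpeciesSignature(
            SPECIES_COSYRA,
            LengthWindow(2, 2),
            confounders=(("Ceratitis pallidula", 97.04), ("Ceratitis quinaria", 96.45)),
        ),
        SpeciesSignature(
            SPECIES_QUILICII,
            LengthWindow(62, 64),
            igs2_window=LengthWindow(16, 18),
            confounders=(("Ceratitis fasciventris", 100.0), ("Ceratitis anonae", 97.78)),
        ),
        SpeciesSignature(
            SPECIES_ROSA,
            LengthWindow(34, 34),
            igs2_window=LengthWindow(18, 22),
        ),
        SpeciesSignature(
            SPECIES_DORSALIS,
            LengthWindow(0, 0),
            confounders=(
                ("Bactrocera invadens", 99.51),
                ("Bactrocera carambolae", 99.51),
                ("Bactrocera philippinensis", 99.51),
                ("Bactrocera papayae", 99.51),
                ("Bactrocera ruiliensis", 97.57),
                ("Bactrocera thailandica", 97.57),
            ),
        ),
    ]
    return SignatureTable(entries=entries, tolerance=tolerance)


def validate_table(table: SignatureTable) -> list[str]:
    """Structural validation; returns human-readable violations (empty = valid)."""
    violations: list[str] = []
    if not table.entries:
        violations.append("table has no entries")
        return violations
    if table.tolerance < 0:
        violations.append("tolerance is negative")
    seen: set[str] = set()
    for e in table.entries:
        key = e.species.lower()
        if key in seen:
            violations.append(f"duplicate species {e.species}")
        seen.add(key)
        for label, window in (("igs1", e.igs1_window), ("igs2", e.igs2_window)):
            if window is None:
                continue
            if window.min_len < 0 or window.max_len < 0:
                violations.append(f"{e.species} {label} window has negative bound")
            if window.min_len > window.max_len:
                violations.append(
                    f"{e.species} {label} window min {window.min_len} > max {window.max_len}"
                )
        for taxon, pct in e.confounders:
            if not 0 < pct <= 100:
                violations.append(
                    f"{e.species} confounder {taxon} identity {pct} outside (0, 100]"
                )
    tol = max(table.tolerance, 0)
    for i, a in enumerate(table.entries):
        for b in table.entries[i + 1:]:
            ea = a.igs1_window.expand(tol)
            eb = b.igs1_window.expand(tol)
            if ea.overlaps(eb):
                violations.append(
                    f"expanded IGS-I windows of {a.species} {ea.as_tuple()} and "
                    f"{b.species} {eb.as_tuple()} overlap at tolerance {tol}"
                )
    return violations
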
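"""File I/O: FASTA round-tripping, GenBank flat-file parsing, report writing.

Conventions: internal coordinates are 0-based half-open; everything written
to reports (and everything parsed from GenBank) is 1-based inclusive.  Every
report echoes the tool version and the signature-table digest so a run is
fully attributable to (config, seed, table).
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from . import __version__
from .seqs import IUPAC_ALPHABET
from .signatures import SignatureTable, build_default_table

FASTA_WRAP = 70


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse a FASTA file to (id, sequence) pairs, validating the alphabet.

    Invalid symbols are reported with their line number in the file.
    """
    path = Path(path)
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(path, "fasta")]
    bad = [
        (rid, {c for c in seq if c not in IUPAC_ALPHABET})
        for rid, seq in records
        if any(c not in IUPAC_ALPHABET for c in seq)
    ]
    if bad:
        rid, symbols = bad[0]
        symbol = sorted(symbols)[0]
        line_no = _find_symbol_line(path, symbol)
        raise ValueError(
            f"{path}:{line_no}: invalid nucleotide symbol {symbol!r} in record {rid!r}"
        )
    return records


def _find_symbol_line(path: Path, symbol: str) -> int:
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith(">") and symbol in line.upper():
            return i
    return 0


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs wrapped at 70 columns."""
    seq_records = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    with open(path, "w") as handle:
        FastaWriter(handle, wrap=FASTA_WRAP).write_file(seq_records)


@dataclass(frozen=True)
class GenomeFeature:
    type: str
    label: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: int


@dataclass
class AnnotatedGenome:
    id: str
    sequence: str
    circular: bool
    features: list[GenomeFeature]

    def trna_features(self) -> list[GenomeFeature]:
        return [f for f in self.features if f.type == "tRNA"]


def read_annotated_genome(path: str | Path) -> AnnotatedGenome:
    """Parse a GenBank flat file into an AnnotatedGenome."""
    record = SeqIO.read(path, "genbank")
    sequence = str(record.seq).upper()
    if not sequence or set(sequence) == {"N"}:
        raise ValueError(f"{path}: flat file carries no sequence")
    declared = record.annotations.get("sequence_length")
    features: list[GenomeFeature] = []
    for feat in record.features:
        if feat.type not in ("tRNA", "rRNA", "gene", "CDS"):
            continue
        label = (
            feat.qualifiers.get("product", [""])[0]
            or feat.qualifiers.get("gene", [""])[0]
            or feat.qualifiers.get("note", [""])[0]
        )
        features.append(
            GenomeFeature(
                type=feat.type,
                label=label,
                start=int(feat.location.start) + 1,
                end=int(feat.location.end),
                strand=int(feat.location.strand or 1),
            )
        )
    circular = record.annotations.get("topology", "linear") == "circular"
    return AnnotatedGenome(
        id=record.id or record.name,
        sequence=sequence,
        circular=circular,
        features=features,
    )


_TRNA_PATTERNS = {
    "ile": re.compile(r"ile|trn[-_ ]?i\b", re.IGNORECASE),
    "gln": re.compile(r"gln|trn[-_ ]?q\b", re.IGNORECASE),
    "met": re.compile(r"met|trn[-_ ]?m\b", re.IGNORECASE),
}


def trna_refs_from_annotation(genome: AnnotatedGenome,
                              amplicon_interval: tuple[int, int]):
    """Build a TrnaReferenceSet from a genome's tRNA-Ile/Gln/Met annotation,
    trimmed to the amplicon-internal portions.

    References are taken in amplicon (plus-strand) orientation regardless of
    the annotated gene strand, since anchoring operates on the amplicon's
    forward-primer strand.
    """
    from .dissect import TrnaReferenceSet

    amp_start, amp_end = amplicon_interval  # 0-based half-open
    found: dict[str, str] = {}
    for key, pattern in _TRNA_PATTERNS.items():
        for feat in genome.trna_features():
            if not pattern.search(feat.label):
                continue
            f_start, f_end = feat.start - 1, feat.end  # to 0-based half-open
            lo, hi = max(f_start, amp_start), min(f_end, amp_end)
            if hi - lo <= 0:
                continue
            found[key] = genome.sequence[lo:hi]
            break
    missing = [k for k in _TRNA_PATTERNS if k not in found]
    if missing:
        raise ValueError(
            f"annotation of {genome.id} lacks usable tRNA features for: "
            + ", ".join(missing)
        )
    return TrnaReferenceSet(
        ile=found["ile"], gln=found["gln"], met=found["met"],
        source=f"annotation of {genome.id}",
    )


def at_fraction_pct(sequence: str) -> float:
    """AT content in percent, 3 decimals (matching assembly-report precision)."""
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    return round(100.0 * (seq.count("A") + seq.count("T")) / len(seq), 3)


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

def report_header(seed: Optional[int] = None,
                  table: Optional[SignatureTable] = None) -> list[str]:
    table = table or build_default_table()
    lines = [f"# igstyper {__version__}",
             f"# signature_table_sha256={table.sha256()}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    return lines


def write_tsv(path: str | Path, columns: Sequence[str],
              rows: Iterable[Sequence], seed: Optional[int] = None,
              table: Optional[SignatureTable] = None) -> None:
    lines = report_header(seed, table)
    lines.append("\t".join(columns))
    for row in rows:
        lines.append("\t".join("" if v is None else str(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_json_report(path: str | Path, payload: dict,
                      seed: Optional[int] = None,
                      table: Optional[SignatureTable] = None) -> None:
    table = table or build_default_table()
    doc = {
        "tool": "igstyper",
        "version": __version__,
        "signature_table_sha256": table.sha256(),
    }
    if seed is not None:
        doc["seed"] = seed
    doc.update(payload)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
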
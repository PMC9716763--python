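import random

import pytest

from igstyper.seqs import IUPAC_BITS, reverse_complement
from igstyper.signatures import build_default_table


@pytest.fixture(scope="session")
def table():
    return build_default_table()


@pytest.fixture(scope="session")
def species_list(table):
    return table.species()


def naive_primer_scan(template, circular, primer_seq, max_mismatch):
    """Independent brute-force oracle: sliding-window IUPAC mismatch count at
    every start and strand, origin handled by explicit doubling."""
    m = len(primer_seq)
    n = len(template)
    probes = {"+": primer_seq.upper(), "-": reverse_complement(primer_seq.upper())}
    doubled = template.upper() + (template.upper() if circular else "")
    hits = []
    limit = n if circular else n - m + 1
    for start in range(max(limit, 0)):
        window = doubled[start:start + m]
        if len(window) < m:
            continue
        for strand, probe in probes.items():
            mism = sum(
                1
                for w, p in zip(window, probe)
                if not (IUPAC_BITS.get(w, 0) & IUPAC_BITS.get(p, 0))
            )
            if mism <= max_mismatch:
                hits.append((strand, start, mism))
    return sorted(hits)


def random_iupac_template(rng: random.Random, length: int, degenerate=False) -> str:
    alphabet = "ACGT" if not degenerate else "ACGTN"
    return "".join(rng.choice(alphabet) for _ in range(length))


@pytest.fixture(scope="session")
def primer_scan_oracle():
    return naive_primer_scan
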
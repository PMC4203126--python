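"""Exact IUPAC consensus matching on promoter sequences.

Matching is literal degenerate-alphabet matching, not PWM scoring: a motif
position matches a base iff the base belongs to the IUPAC class at that
position.  ``N`` in a *sequence* never matches anything (unknown base);
``N`` in a *motif* matches any of ACGT.  Both strands are scanned, a
reverse-complement match being counted at its forward-strand position, so a
palindromic motif counts twice per physical site (once per strand).
"""

from __future__ import annotations

import re

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_regex(motif: str) -> re.Pattern:
    """Compile a motif to a regex over ACGT; rejects non-IUPAC characters."""
    motif = motif.upper()
    bad = [c for c in motif if c not in IUPAC]
    if bad:
        raise ValueError(f"motif {motif!r} has non-IUPAC characters: {bad}")
    parts = []
    for c in motif:
        opts = IUPAC[c]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("".join(parts))


def scan_sequence(seq: str, motif: str) -> int:
    """Count exact IUPAC matches of ``motif`` in ``seq`` on both strands.

    Overlapping occurrences all count.  Positions are 0-based half-open on
    the forward strand; only the count is returned.
    """
    seq = seq.upper()
    n = 0
    for pattern in (iupac_regex(motif), iupac_regex(reverse_complement(motif))):
        pos = 0
        while True:
            m = pattern.search(seq, pos)
            if m is None:
                break
            n += 1
            pos = m.start() + 1
    return n


def match_positions(seq: str, motif: str) -> list[tuple[int, str]]:
    """All (forward-strand position, strand) matches, for diagnostics."""
    seq = seq.upper()
    out: list[tuple[int, str]] = []
    for strand, pattern in (
        ("+", iupac_regex(motif)),
        ("-", iupac_regex(reverse_complement(motif))),
    ):
        pos = 0
        while True:
            m = pattern.search(seq, pos)
            if m is None:
                break
            out.append((m.start(), strand))
            pos = m.start() + 1
    return sorted(out)


def sample_iupac_realization(motif: str, rng: np.random.Generator) -> str:
    """One concrete ACGT word matching the consensus, drawn uniformly."""
    motif = motif.upper()
    bad = [c for c in motif if c not in IUPAC]
    if bad:
        raise ValueError(f"motif {motif!r} has non-IUPAC characters: {bad}")
    return "".join(IUPAC[c][rng.integers(len(IUPAC[c]))] for c in motif)
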
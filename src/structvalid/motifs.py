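"""PROSITE-style motif scanning and fold-enrichment statistics.

Patterns use the PROSITE syntax subset of dash-separated elements: a
residue letter, ``x`` (any residue), ``[ABC]`` (alternatives), ``{ABC}``
(exclusions), with optional ``(n)`` or ``(n,m)`` repetition counts, e.g.
``P-x-L-x-P`` or ``C-x(2,4)-C``.  Every start position is tested
independently, so overlapping occurrences are all reported.

Enrichment of a motif in a protein list is the ratio of observed matches
per protein to the expected random matches per protein in a background
sequence set; significance uses a Poisson count test with mean
λ = n_proteins × background_rate, with Benjamini–Hochberg correction when
several motifs are tested together.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MotifHit",
    "EnrichmentResult",
    "PatternSyntaxError",
    "prosite_to_regex",
    "scan_pattern",
    "enrichment",
    "benjamini_hochberg",
    "read_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class PatternSyntaxError(ValueError):
    """Malformed PROSITE pattern; carries the offending element position."""


@dataclass
class MotifHit:
    sequence_id: str
    start: int  # 1-based
    match: str


@dataclass
class EnrichmentResult:
    n_hits: int
    n_proteins: int
    observed_rate: float  # hits per protein
    background_matches: int
    background_size: int
    background_rate: float  # matches per protein in the background
    fold: float
    p: float
    fdr: float | None = None


_ELEMENT_RE = re.compile(
    r"^(?:(?P<letter>[A-Za-z])|(?P<any>x)|\[(?P<alt>[A-Za-z]+)\]|\{(?P<excl>[A-Za-z]+)\})"
    r"(?:\((?P<n>\d+)(?:,(?P<m>\d+))?\))?$"
)


def prosite_to_regex(pattern: str) -> str:
    """Translate a PROSITE pattern to a Python regular expression."""
    pattern = pattern.strip().rstrip(".")
    prefix = suffix = ""
    if pattern.startswith("<"):
        prefix, pattern = "^", pattern[1:]
    if pattern.endswith(">"):
        suffix, pattern = "$", pattern[:-1]
    parts = pattern.split("-")
    out = []
    for pos, raw in enumerate(parts, start=1):
        m = _ELEMENT_RE.match(raw.strip())
        if not m or not raw.strip():
            raise PatternSyntaxError(f"element {pos} ({raw!r}) is not valid PROSITE syntax")
        if m.group("letter"):
            if m.group("letter").upper() == "X":
                core = "."
            else:
                core = m.group("letter").upper()
        elif m.group("any"):
            core = "."
        elif m.group("alt"):
            core = "[" + m.group("alt").upper() + "]"
        else:
            core = "[^" + m.group("excl").upper() + "]"
        if m.group("n"):
            if m.group("m"):
                lo, hi = int(m.group("n")), int(m.group("m"))
                if hi < lo:
                    raise PatternSyntaxError(f"element {pos}: repetition ({lo},{hi}) reversed")
                core += f"{{{lo},{hi}}}"
            else:
                core += f"{{{int(m.group('n'))}}}"
        out.append(core)
    return prefix + "".join(out) + suffix


def scan_pattern(pattern: str, sequences: dict[str, str] | Iterable[tuple[str, str]]) -> list[MotifHit]:
    """All occurrences of a PROSITE pattern in a set of sequences.

    ``sequences`` maps sequence id to amino-acid string (or yields such
    pairs).  Overlapping occurrences are included: each start position is
    tested independently via a lookahead scan.
    """
    regex = prosite_to_regex(pattern)
    # lookahead makes the scan restart one character after each hit start
    finder = re.compile(f"(?=({regex}))")
    items = sequences.items() if isinstance(sequences, dict) else sequences
    hits: list[MotifHit] = []
    for seq_id, seq in items:
        for m in finder.finditer(seq.upper()):
            hits.append(MotifHit(sequence_id=seq_id, start=m.start() + 1, match=m.group(1)))
    return hits


def enrichment(
    n_hits: int,
    n_proteins: int,
    background_matches: int = 10318,
    background_size: int = 100000,
) -> EnrichmentResult:
    """Fold enrichment of motif matches over a sequence background.

    fold = (n_hits / n_proteins) / (background_matches / background_size);
    p = P(X ≥ n_hits) for X ~ Poisson(n_proteins × background_rate).
    """
    if n_hits < 0 or n_proteins < 1 or background_size < 1:
        raise ValueError("counts must be non-negative, with at least one protein")
    background_rate = background_matches / background_size
    if background_rate <= 0:
        raise ValueError("background rate is zero: enrichment undefined")
    observed_rate = n_hits / n_proteins
    lam = n_proteins * background_rate
    p = float(stats.poisson.sf(n_hits - 1, lam))  # P(X >= n_hits)
    return EnrichmentResult(
        n_hits=n_hits,
        n_proteins=n_proteins,
        observed_rate=observed_rate,
        background_matches=background_matches,
        background_size=background_size,
        background_rate=background_rate,
        fold=observed_rate / background_rate,
        p=p,
    )


def benjamini_hochberg(results: Sequence[EnrichmentResult]) -> list[EnrichmentResult]:
    """Attach Benjamini–Hochberg FDR values to a batch of enrichment tests."""
    ps = np.array([r.p for r in results])
    fdrs = stats.false_discovery_control(ps, method="bh")
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
    return list(results)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file as an id -> sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
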
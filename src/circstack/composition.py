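"""Nucleotide-composition features: k-mer frequencies and ORF statistics.

Two feature groups live here:

* trinucleotide (k = 3) frequencies ``f(t) = N(t) / N`` over the 64 k-mers
  in lexicographic order, where N is the *sequence length* (not the window
  count) — windows containing an ambiguous base N contribute to no component;
* four open-reading-frame statistics derived from the longest complete ORF
  (ATG through the first in-frame stop) in each of the three forward frames:
  ORF length, ORF coverage, ORF average coverage, and the ORF difference
  d = ((x0-x1)^2 + (x0-x2)^2 + (x1-x2)^2) / 2 over the per-frame coverages.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

BASES = "ACGT"
KMER_NAMES_3 = ["".join(p) for p in product(BASES, repeat=3)]

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}


class InputError(ValueError):
    """Invalid input to a feature encoder."""


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a normalized sequence to integer codes (A=0..T=3, N=-1)."""
    try:
        return np.fromiter(
            (_BASE_CODE[c] for c in sequence), dtype=np.int64, count=len(sequence)
        )
    except KeyError as exc:
        raise InputError(f"invalid base {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class KmerVector:
    """64 trinucleotide frequencies plus the length used as denominator."""

    values: np.ndarray
    n: int

    def as_dict(self) -> dict[str, float]:
        return dict(zip(KMER_NAMES_3, self.values))


def kmer_frequencies(sequence: str, k: int = 3) -> KmerVector:
    """Overlapping k-mer counts divided by the sequence length.

    The denominator is the full sequence length N, so on an N-free sequence
    the components sum to (N - k + 1) / N rather than 1. Windows containing
    an N are skipped.
    """
    n = len(sequence)
    if n < k:
        raise InputError(f"sequence length {n} < k = {k}")
    codes = encode_sequence(sequence)
    # rolling base-4 code of each window; windows touching N are masked out
    window_codes = np.zeros(n - k + 1, dtype=np.int64)
    valid = np.ones(n - k + 1, dtype=bool)
    for j in range(k):
        part = codes[j : n - k + 1 + j]
        valid &= part >= 0
        window_codes = window_codes * 4 + np.where(part >= 0, part, 0)
    counts = np.bincount(window_codes[valid], minlength=4**k).astype(float)
    return KmerVector(values=counts / n, n=n)


def longest_orf_per_frame(sequence: str) -> tuple[int, int, int]:
    """Longest complete ORF length (nt, incl. start and stop codons) per
    forward frame offset 0/1/2; 0 when a frame has no ATG..stop span."""
    seq = sequence
    L = len(seq)
    best = [0, 0, 0]
    for frame in range(3):
        longest = 0
        pos = frame
        open_start: int | None = None
        while pos + 3 <= L:
            codon = seq[pos : pos + 3]
            if open_start is None:
                if codon == START_CODON:
                    open_start = pos
            elif codon in STOP_CODONS:
                longest = max(longest, pos + 3 - open_start)
                open_start = None
            pos += 3
        best[frame] = longest
    return tuple(best)  # type: ignore[return-value]


@dataclass(frozen=True)
class ORFFeatures:
    orf_length: int
    orf_coverage: float
    orf_avg_coverage: float
    orf_difference: float
    per_frame: tuple[int, int, int]

    def as_dict(self) -> dict[str, float]:
        return {
            "orf_length": float(self.orf_length),
            "orf_coverage": self.orf_coverage,
            "orf_avg_coverage": self.orf_avg_coverage,
            "orf_difference": self.orf_difference,
        }


def orf_difference(x0: float, x1: float, x2: float) -> float:
    """Pairwise squared-difference spread of the three frame values."""
    return ((x0 - x1) ** 2 + (x0 - x2) ** 2 + (x1 - x2) ** 2) / 2.0


def orf_features(sequence: str) -> ORFFeatures:
    """The four ORF statistics of a transcript.

    The per-frame values entering the difference statistic are coverages
    (frame ORF length / transcript length), keeping the spread comparable
    across transcript lengths.
    """
    L = len(sequence)
    if L == 0:
        raise InputError("empty sequence")
    frames = longest_orf_per_frame(sequence)
    cov = [f / L for f in frames]
    return ORFFeatures(
        orf_length=max(frames),
        orf_coverage=max(frames) / L,
        orf_avg_coverage=sum(frames) / 3.0 / L,
        orf_difference=orf_difference(*cov),
        per_frame=frames,
    )
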
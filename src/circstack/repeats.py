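"""Repeat-derived features: Alu flank counts and tandem-repeat frequency.

Alu enrichment in the introns flanking a back-splice junction promotes
circularization, so the pipeline counts Alu elements in fixed genomic
windows upstream of the acceptor-side coordinate and downstream of the
donor-side coordinate (1000 nt and 2000 nt by default). Tandem repeats
promote reverse splicing within genes; a deterministic exact-match
detector reports the density of short tandem-repeat copies per kilobase
of transcript sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .seqio import AnnotationIntervalSet, GenomicLocus

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class RepeatFeatures:
    alu_counts: dict[int, int]  # window size -> count
    tandem_repeat_freq: float

    @property
    def alu_total(self) -> int:
        return sum(self.alu_counts.values())


def alu_flank_counts(
    locus: GenomicLocus | None,
    alu: AnnotationIntervalSet,
    window_sizes: Sequence[int] = (1000, 2000),
) -> dict[int, int]:
    """Count Alu elements overlapping the two windows flanking a back-splice site.

    For window size W the flanks are [start - W, start) and [end, end + W),
    clipped at coordinate 0. An element overlapping both flanks is counted
    once per window size. Transcripts without a locus (e.g. linear lncRNAs,
    which have no back-splice site) score 0 in every window.
    """
    if any(w <= 0 for w in window_sizes):
        raise ConfigurationError("window sizes must be positive")
    if locus is None:
        return {w: 0 for w in window_sizes}
    if locus.chrom not in alu.intervals:
        logger.warning("chromosome %s absent from Alu annotation; count 0", locus.chrom)
        return {w: 0 for w in window_sizes}
    ivs = alu.intervals[locus.chrom]
    out: dict[int, int] = {}
    for w in window_sizes:
        up = (max(0, locus.start - w), locus.start)
        down = (locus.end, locus.end + w)
        n = 0
        for s, e in ivs:
            if s >= down[1]:
                break
            hits_up = up[0] < up[1] and s < up[1] and e > up[0]
            hits_down = s < down[1] and e > down[0]
            if hits_up or hits_down:
                n += 1
        out[w] = n
    return out


def tandem_repeat_frequency(
    sequence: str,
    min_period: int = 1,
    max_period: int = 6,
    min_copies: int = 3,
) -> float:
    """Exact short-tandem-repeat density in copies per kilobase.

    Scans for maximal runs in which a motif of period p in
    [min_period, max_period] repeats exactly at least ``min_copies`` times.
    Periods are scanned smallest first, and a run overlapping positions
    already claimed by a smaller-period run is suppressed, so e.g. a
    homopolymer is called once at period 1 and never again at period 2.
    Returns (total repeat copies across runs) * 1000 / sequence length.
    """
    if min_period > max_period:
        raise ConfigurationError("min_period must be <= max_period")
    if min_period < 1:
        raise ConfigurationError("min_period must be >= 1")
    L = len(sequence)
    if L == 0:
        raise ConfigurationError("empty sequence")
    covered = bytearray(L)
    total_copies = 0
    for p in range(min_period, max_period + 1):
        i = p
        run_start = 0
        while i <= L:
            # extend the current run while s[i] == s[i - p]
            if i < L and sequence[i] == sequence[i - p]:
                i += 1
                continue
            run_len = i - run_start
            copies = run_len // p
            if copies >= min_copies:
                span = (run_start, run_start + copies * p)
                if not any(covered[span[0] : span[1]]):
                    total_copies += copies
                    for j in range(span[0], span[1]):
                        covered[j] = 1
            run_start = i - p + 1
            i = run_start + p
    return total_copies * 1000.0 / L


def repeat_features(
    record_sequence: str,
    locus: GenomicLocus | None,
    alu: AnnotationIntervalSet,
    window_sizes: Sequence[int] = (1000, 2000),
    min_period: int = 1,
    max_period: int = 6,
    min_copies: int = 3,
) -> RepeatFeatures:
    return RepeatFeatures(
        alu_counts=alu_flank_counts(locus, alu, window_sizes),
        tandem_repeat_freq=tandem_repeat_frequency(
            record_sequence, min_period, max_period, min_copies
        ),
    )
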
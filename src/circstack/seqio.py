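"""Sequence and interval I/O plus the core transcript data model.

Transcripts are held as :class:`TranscriptRecord` objects: an id, a
normalized nucleotide sequence (uppercase DNA alphabet, U mapped to T),
an optional class label (1 = circRNA, 0 = lncRNA) and an optional
:class:`GenomicLocus` carrying the genomic span of the circularized
interval, whose endpoints are the back-splice-junction coordinates used
for Alu flank counting.

Alu annotations are plain BED3 intervals grouped per chromosome in an
:class:`AnnotationIntervalSet`.

Also provides a deterministic greedy redundancy filter
(:func:`reduce_redundancy`) that approximates CD-HIT-style clustering at
a fractional identity cutoff using shared-word identity.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")

POSITIVE_LABEL = 1  # circRNA
NEGATIVE_LABEL = 0  # other lncRNA


class FormatError(ValueError):
    """A file does not conform to the expected format."""


class ValidationError(ValueError):
    """A record violates a data-model invariant."""


@dataclass(frozen=True)
class GenomicLocus:
    """Half-open 0-based genomic interval of a circularized transcript.

    ``start`` is the acceptor-side and ``end`` the donor-side coordinate of
    the back-splice junction; the 1000/2000-nt Alu windows flank these two
    endpoints.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid locus {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript: id, normalized sequence, optional label and locus."""

    id: str
    sequence: str
    label: int | None = None
    locus: GenomicLocus | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValidationError(
                f"record {self.id!r}: invalid characters {sorted(bad)} "
                "(expected A/C/G/T/N after normalization)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_sequence(raw: str) -> str:
    """Uppercase and map U->T (RNA and DNA FASTA both occur in practice)."""
    return raw.upper().replace("U", "T")


@dataclass
class AnnotationIntervalSet:
    """Per-chromosome sorted half-open intervals (e.g. Alu elements)."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, ivs in self.intervals.items():
            for s, e in ivs:
                if s >= e:
                    raise ValidationError(
                        f"interval {chrom}:{s}-{e}: start must be < end"
                    )
            ivs.sort()

    def __len__(self) -> int:
        return sum(len(v) for v in self.intervals.values())

    def count_overlapping(self, chrom: str, start: int, end: int) -> int:
        """Count intervals overlapping [start, end) by >= 1 bp."""
        ivs = self.intervals.get(chrom)
        if ivs is None:
            return 0
        # intervals are sorted by start; scan the candidate slice
        starts = [s for s, _ in ivs]
        hi = bisect_left(starts, end)
        return sum(1 for s, e in ivs[:hi] if e > start)


def read_fasta(path: str | Path) -> list[TranscriptRecord]:
    """Read transcripts from FASTA, normalizing sequences.

    Raises FormatError on an empty file and ValidationError on records
    with characters outside {A,C,G,T,N,U} (case-insensitive).
    """
    path = Path(path)
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(rec.seq))
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(TranscriptRecord(id=rec.id, sequence=seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_bed_intervals(path: str | Path) -> AnnotationIntervalSet:
    """Read BED3+ intervals (0-based half-open); extra columns ignored."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2], comment="#",
            names=["chrom", "start", "end"],
            dtype={"chrom": str, "start": int, "end": int},
        )
    except pd.errors.EmptyDataError:
        return AnnotationIntervalSet({})
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: malformed BED: {exc}") from exc
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        line = int(bad[0]) + 1
        raise FormatError(f"{path}: line {line}: start >= end")
    grouped: dict[str, list[tuple[int, int]]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        grouped[str(chrom)] = sorted(zip(sub["start"], sub["end"]))
    return AnnotationIntervalSet(grouped)


def write_bed_intervals(alu: AnnotationIntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(alu.intervals):
            for s, e in alu.intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def write_bed_loci(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Write transcript loci as BED6; the name field carries the id and the
    score field the class label (-1 when unlabeled)."""
    with open(path, "w") as fh:
        for r in records:
            if r.locus is None:
                continue
            lab = -1 if r.label is None else r.label
            fh.write(
                f"{r.locus.chrom}\t{r.locus.start}\t{r.locus.end}"
                f"\t{r.id}\t{lab}\t{r.locus.strand}\n"
            )


def read_bed_loci(path: str | Path) -> dict[str, tuple[GenomicLocus, int | None]]:
    """Read BED6 transcript loci written by :func:`write_bed_loci`."""
    out: dict[str, tuple[GenomicLocus, int | None]] = {}
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
    except pd.errors.EmptyDataError:
        return out
    for row in df.itertuples(index=False):
        label = None if int(row.score) < 0 else int(row.score)
        out[str(row.name)] = (
            GenomicLocus(str(row.chrom), int(row.start), int(row.end), str(row.strand)),
            label,
        )
    return out


def attach_loci(
    records: Sequence[TranscriptRecord],
    loci: dict[str, tuple[GenomicLocus, int | None]],
) -> list[TranscriptRecord]:
    """Return records with locus (and label, when present) filled from a BED6 map."""
    out = []
    for r in records:
        if r.id in loci:
            locus, label = loci[r.id]
            out.append(replace(r, locus=locus, label=label if r.label is None else r.label))
        else:
            out.append(r)
    return out


def filter_min_length(
    records: Sequence[TranscriptRecord], min_len: int = 200
) -> list[TranscriptRecord]:
    """Keep transcripts of length >= min_len (the standard lncRNA cutoff)."""
    return [r for r in records if len(r) >= min_len]


def _word_multiset(seq: str, word_size: int) -> Counter:
    return Counter(seq[i : i + word_size] for i in range(len(seq) - word_size + 1))


def word_identity(a: str, b: str, word_size: int = 5) -> float:
    """Shared-word identity: |shared word multiset| / |words of shorter sequence|.

    A cheap, deterministic proxy for pairwise sequence identity; 1.0 for
    identical sequences, 0.0 when no word is shared.
    """
    if min(len(a), len(b)) < word_size:
        return 1.0 if a == b else 0.0
    wa, wb = _word_multiset(a, word_size), _word_multiset(b, word_size)
    shared = sum((wa & wb).values())
    shorter = min(len(a), len(b)) - word_size + 1
    return shared / shorter


def reduce_redundancy(
    records: Sequence[TranscriptRecord],
    identity_threshold: float = 0.8,
    word_size: int = 5,
) -> list[TranscriptRecord]:
    """Greedy longest-first redundancy reduction at a word-identity cutoff.

    Records are visited in descending length order (ties by id); a record is
    dropped when its word identity to any already-retained record reaches
    ``identity_threshold``. Deterministic; output preserves the original
    input order of the retained records.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    order = sorted(records, key=lambda r: (-len(r), r.id))
    retained: list[TranscriptRecord] = []
    for rec in order:
        if all(
            word_identity(rec.sequence, kept.sequence, word_size) < identity_threshold
            for kept in retained
        ):
            retained.append(rec)
    kept_ids = {r.id for r in retained}
    return [r for r in records if r.id in kept_ids]
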
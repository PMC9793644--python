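"""Synthetic labeled datasets for exercising the whole pipeline.

Real circRNA/lncRNA corpora need genome and annotation downloads; this
module instead emulates the signal classes the feature groups are built
to detect, with controllable separation between the two classes:

* background sequence from a second-order Markov chain (so dinucleotide
  and trinucleotide structure is non-trivial), with a configurable
  enrichment factor for a chosen trinucleotide set in positives;
* complete ORFs (ATG + stop-free codons + stop) planted with
  class-specific probabilities;
* short tandem-repeat runs planted at class-specific densities per kb;
* a synthetic chromosome on which every transcript owns a disjoint slab,
  with Poisson-distributed ~300-bp Alu elements dropped into the 2000-nt
  windows flanking its back-splice coordinates at class-specific rates.

Everything is deterministic under the config seed, and a per-record
manifest reports every planted element so recovery can be audited.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .seqio import (
    AnnotationIntervalSet,
    GenomicLocus,
    TranscriptRecord,
    write_bed_intervals,
    write_bed_loci,
    write_fasta,
)

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_ALU_LENGTH = 300
_FLANK = 2000  # Alu placement window per side
_SLAB_GAP = 1000

# CpG-containing trinucleotides: a compact, biologically evocative set to
# enrich in positives
DEFAULT_BIASED_TRINUCS = ("ACG", "CCG", "GCG", "TCG", "CGA", "CGC", "CGG", "CGT")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic benchmark (defaults: strong
    class separation on every feature group)."""

    n_pos: int = 1000
    n_neg: int = 1000
    length_range: tuple[int, int] = (200, 3000)
    gc_content: float = 0.42
    trinucleotide_bias: float = 3.0
    biased_trinucs: tuple[str, ...] = DEFAULT_BIASED_TRINUCS
    orf_prob_pos: float = 0.9
    orf_prob_neg: float = 0.1
    tandem_density_pos: float = 1.0  # planted runs per kb
    tandem_density_neg: float = 0.1
    alu_rate_pos: float = 3.0  # expected Alu elements per flanking window pair
    alu_rate_neg: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 200 or hi < lo:
            raise ValueError("length_range must satisfy 200 <= min <= max")
        for p in (self.orf_prob_pos, self.orf_prob_neg):
            if not 0 <= p <= 1:
                raise ValueError("ORF probabilities must be in [0, 1]")


def null_config(n_pos: int = 500, n_neg: int = 500, seed: int = 0) -> SimulationConfig:
    """No class-separating signal: both classes drawn from one process."""
    return SimulationConfig(
        n_pos=n_pos,
        n_neg=n_neg,
        trinucleotide_bias=1.0,
        orf_prob_pos=0.3,
        orf_prob_neg=0.3,
        tandem_density_pos=0.3,
        tandem_density_neg=0.3,
        alu_rate_pos=1.0,
        alu_rate_neg=1.0,
        seed=seed,
    )


def _transition_cum(
    gc: float, bias: float, biased: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Base marginals and cumulative second-order transition matrix.

    T[prev_pair, next] ∝ p_base(next) * bias if (prev_pair + next) is a
    biased trinucleotide, else p_base(next).
    """
    p_base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = {b: i for i, b in enumerate(_BASES)}
    T = np.tile(p_base, (16, 1))
    for tri in biased:
        pair = idx[tri[0]] * 4 + idx[tri[1]]
        T[pair, idx[tri[2]]] *= bias
    T /= T.sum(axis=1, keepdims=True)
    return p_base, np.cumsum(T, axis=1)


def _markov_batch(
    rng: np.random.Generator, lengths: np.ndarray, p_base: np.ndarray, cumT: np.ndarray
) -> np.ndarray:
    """Generate a (n, max_len) int8 code matrix of Markov sequences."""
    n, lmax = len(lengths), int(lengths.max())
    codes = np.zeros((n, lmax), dtype=np.int8)
    cum0 = np.cumsum(p_base)
    for pos in range(2):
        codes[:, pos] = np.searchsorted(cum0, rng.random(n), side="right")
    state = codes[:, 0].astype(np.int64) * 4 + codes[:, 1]
    for pos in range(2, lmax):
        u = rng.random(n)
        nxt = (cumT[state] < u[:, None]).sum(axis=1)
        codes[:, pos] = nxt
        state = (state % 4) * 4 + nxt
    return codes


def _encode(s: str) -> np.ndarray:
    return np.array([_BASES.index(c) for c in s], dtype=np.int8)


def _decode(codes: np.ndarray) -> str:
    lookup = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lookup[codes.astype(np.intp)].tobytes().decode()


def _random_orf_codes(rng: np.random.Generator, n_codons: int) -> np.ndarray:
    """ATG, n_codons stop-free random codons, then a random stop codon."""
    body = []
    stop_set = set(_STOPS)
    while len(body) < n_codons:
        codon = "".join(_BASES[i] for i in rng.integers(0, 4, size=3))
        if codon not in stop_set:
            body.append(codon)
    return _encode("ATG" + "".join(body) + _STOPS[rng.integers(0, 3)])


def _plant(codes: np.ndarray, insert: np.ndarray, pos: int) -> None:
    codes[pos : pos + len(insert)] = insert


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[TranscriptRecord], AnnotationIntervalSet, dict]:
    """Generate labeled transcripts, their Alu annotation, and a truth manifest."""
    rng = np.random.default_rng(config.seed)
    n_total = config.n_pos + config.n_neg
    labels = np.array([1] * config.n_pos + [0] * config.n_neg)
    lengths = rng.integers(config.length_range[0], config.length_range[1] + 1, size=n_total)

    _, cum_neutral = _transition_cum(config.gc_content, 1.0, config.biased_trinucs)
    p_base, cum_biased = _transition_cum(
        config.gc_content, config.trinucleotide_bias, config.biased_trinucs
    )
    codes = np.zeros((n_total, int(lengths.max())), dtype=np.int8)
    pos_mask = labels == 1
    for mask, cum in ((pos_mask, cum_biased), (~pos_mask, cum_neutral)):
        if mask.any():
            batch = _markov_batch(rng, lengths[mask], p_base, cum)
            codes[np.where(mask)[0][:, None], np.arange(batch.shape[1])] = batch

    records: list[TranscriptRecord] = []
    alu_intervals: list[tuple[int, int]] = []
    manifest: dict[str, dict] = {}
    cursor = 10_000  # left margin on the synthetic chromosome
    chrom = "chrS"
    for i in range(n_total):
        L = int(lengths[i])
        label = int(labels[i])
        row = codes[i, :L].copy()
        orf_prob = config.orf_prob_pos if label else config.orf_prob_neg
        tandem_density = config.tandem_density_pos if label else config.tandem_density_neg
        alu_rate = config.alu_rate_pos if label else config.alu_rate_neg

        planted_runs = []
        n_runs = rng.poisson(tandem_density * L / 1000.0)
        for _ in range(n_runs):
            p = int(rng.integers(1, 7))
            copies = int(rng.integers(3, 9))
            motif = rng.integers(0, 4, size=p).astype(np.int8)
            run = np.tile(motif, copies)
            if len(run) >= L:
                continue
            at = int(rng.integers(0, L - len(run) + 1))
            _plant(row, run, at)
            planted_runs.append({"pos": at, "period": p, "copies": copies})

        planted_orf = None
        if rng.random() < orf_prob:
            frac = rng.uniform(0.3, 0.6)
            n_codons = max(10, int(frac * L / 3) - 2)
            orf = _random_orf_codes(rng, n_codons)
            if len(orf) < L:
                at = int(rng.integers(0, L - len(orf) + 1))
                _plant(row, orf, at)
                planted_orf = {"pos": at, "length": int(len(orf))}

        span = int(rng.integers(1000, 20001))
        start = cursor + _FLANK
        end = start + span
        locus = GenomicLocus(chrom, start, end, "+" if rng.random() < 0.5 else "-")
        n_alu = int(rng.poisson(alu_rate))
        flanks = [(start - _FLANK, start), (end, end + _FLANK)]
        for _ in range(n_alu):
            side = flanks[int(rng.integers(0, 2))]
            a0 = int(rng.integers(side[0], side[1]))
            alu_intervals.append((a0, a0 + _ALU_LENGTH))
        cursor = end + _FLANK + _ALU_LENGTH + _SLAB_GAP

        rec_id = f"{'circ' if label else 'lnc'}_{i:05d}"
        records.append(
            TranscriptRecord(id=rec_id, sequence=_decode(row), label=label, locus=locus)
        )
        manifest[rec_id] = {
            "label": label,
            "length": L,
            "planted_orf": planted_orf,
            "planted_tandem_runs": planted_runs,
            "n_alu": n_alu,
            "locus": [chrom, start, end],
        }

    alu = AnnotationIntervalSet({chrom: sorted(alu_intervals)})
    return records, alu, {"config": asdict(config), "records": manifest}


def write_fixture(
    records: list[TranscriptRecord],
    alu: AnnotationIntervalSet,
    manifest: dict,
    directory: str | Path,
) -> dict[str, Path]:
    """Write FASTA, BED6 loci, BED3 Alu and the JSON manifest to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": directory / "transcripts.fa",
        "loci": directory / "loci.bed",
        "alu": directory / "alu.bed",
        "manifest": directory / "manifest.json",
    }
    write_fasta(records, paths["fasta"])
    write_bed_loci(records, paths["loci"])
    write_bed_intervals(alu, paths["alu"])
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths
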
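"""Physicochemical sequence encodings: DAC/DCC/DACC and SCPseDNC.

Both encoders map a transcript onto the series of dinucleotide
physicochemical property values along the sequence, using six B-DNA
helical-geometry indices — three angular (Twist, Tilt, Roll) and three
translational (Shift, Slide, Rise) steps between adjacent base pairs.

* DAC (dinucleotide auto covariance) measures, for one property u and a
  lag, the mean-centred covariance of the property series with itself at
  that lag:

      DAC(u, lag) = sum_i (P_u(i) - Pbar_u)(P_u(i+lag) - Pbar_u) / (L - lag - 1)

  DCC (cross covariance) does the same between two distinct properties.
  Their concatenation DACC has dimension N_props^2 * LAG.

* SCPseDNC (series-correlation pseudo dinucleotide composition) extends
  the 16 dinucleotide frequencies with lambda * Lambda tiered correlation
  factors theta, each the average product of one property's values at two
  positions a fixed distance apart, combined through a shared weighted
  denominator so the vector sums to one.

The six properties have no canonical unit system; the shipped default
table is the widely used standardized B-DNA dinucleotide parameter set,
and any complete 16 x 6 table can be loaded from TSV and standardized.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .composition import InputError, encode_sequence

DINUCLEOTIDES = ["".join(p) for p in product("ACGT", repeat=2)]
PROPERTY_NAMES = ("Twist", "Tilt", "Roll", "Shift", "Slide", "Rise")

# Standardized B-DNA dinucleotide helical parameters (angular steps Twist,
# Tilt, Roll; translational steps Shift, Slide, Rise), one row per
# dinucleotide in lexicographic order. Complementary steps share values up
# to the usual sign conventions; the table is re-standardized on load so
# only relative structure matters.
_DEFAULT_RAW = {
    #        Twist   Tilt   Roll  Shift  Slide   Rise
    "AA": (0.06, 0.50, 0.27, 1.59, 0.11, -0.11),
    "AC": (1.50, 0.50, 0.80, 0.13, 1.29, 1.04),
    "AG": (0.78, 0.36, 0.09, 0.68, -0.24, -0.62),
    "AT": (1.07, 0.22, 0.62, -1.02, 2.51, 1.17),
    "CA": (-1.38, -1.36, -0.27, -0.86, -0.62, -1.25),
    "CC": (0.06, 1.08, 0.09, 0.56, -0.82, 0.24),
    "CG": (-1.66, -1.22, -0.44, -0.82, -0.29, -1.39),
    "CT": (0.78, 0.36, 0.09, 0.68, -0.24, -0.62),
    "GA": (-0.08, 0.50, 0.27, 0.13, -0.39, 0.71),
    "GC": (-0.08, 0.22, 1.33, -0.35, 0.65, 1.59),
    "GG": (0.06, 1.08, 0.09, 0.56, -0.82, 0.24),
    "GT": (1.50, 0.50, 0.80, 0.13, 1.29, 1.04),
    "TA": (-1.23, -2.37, -0.44, -2.24, -1.51, -1.39),
    "TC": (-0.08, 0.50, 0.27, 0.13, -0.39, 0.71),
    "TG": (-1.38, -1.36, -0.27, -0.86, -0.62, -1.25),
    "TT": (0.06, 0.50, 0.27, 1.59, 0.11, -0.11),
}

MAX_N_FRACTION = 0.05  # transcripts with more ambiguity are rejected


class ConfigurationError(ValueError):
    """An incomplete or inconsistent property-table configuration."""


@dataclass(frozen=True)
class PropertyTable:
    """Values of named physicochemical properties for all 16 dinucleotides.

    ``values`` has shape (n_properties, 16), columns in dinucleotide
    lexicographic order AA..TT.
    """

    names: tuple[str, ...]
    values: np.ndarray
    standardized: bool = False

    @classmethod
    def from_dict(cls, table: dict[str, tuple[float, ...]],
                  names: tuple[str, ...] = PROPERTY_NAMES) -> "PropertyTable":
        missing = [d for d in DINUCLEOTIDES if d not in table]
        if missing:
            raise ConfigurationError(f"property table missing dinucleotides {missing}")
        for d, row in table.items():
            if len(row) != len(names):
                raise ConfigurationError(
                    f"dinucleotide {d}: expected {len(names)} property values, got {len(row)}"
                )
        mat = np.array([[table[d][p] for d in DINUCLEOTIDES] for p in range(len(names))],
                       dtype=float)
        return cls(names=tuple(names), values=mat)

    @classmethod
    def default(cls) -> "PropertyTable":
        """The shipped standardized six-property B-DNA table."""
        return standardize_properties(cls.from_dict(_DEFAULT_RAW))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PropertyTable":
        """Load a table from TSV: one row per dinucleotide (index column),
        one named column per property."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        missing = [d for d in DINUCLEOTIDES if d not in df.index]
        if missing:
            raise ConfigurationError(f"{path}: missing dinucleotides {missing}")
        names = tuple(df.columns)
        mat = df.loc[DINUCLEOTIDES].to_numpy(dtype=float).T
        return cls(names=names, values=mat)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values.T, index=DINUCLEOTIDES, columns=list(self.names)).to_csv(
            path, sep="\t", index_label="dinucleotide"
        )

    @property
    def n_properties(self) -> int:
        return len(self.names)


def standardize_properties(raw: PropertyTable) -> PropertyTable:
    """Scale each property to mean 0, variance 1 across the 16 dinucleotides."""
    vals = raw.values
    mean = vals.mean(axis=1, keepdims=True)
    std = vals.std(axis=1, keepdims=True)
    if np.any(std == 0):
        flat = [raw.names[i] for i in np.where(vals.std(axis=1) == 0)[0]]
        raise ConfigurationError(f"properties with zero variance cannot be standardized: {flat}")
    return PropertyTable(names=raw.names, values=(vals - mean) / std, standardized=True)


def _property_series(sequence: str, table: PropertyTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-position property matrix (L-1, n_props) and validity mask.

    Positions whose dinucleotide contains N are flagged invalid; transcripts
    with more than MAX_N_FRACTION ambiguous bases are rejected outright.
    """
    codes = encode_sequence(sequence)
    if len(codes) and (codes < 0).mean() > MAX_N_FRACTION:
        raise InputError(
            f"sequence has >{MAX_N_FRACTION:.0%} ambiguous bases; encoding rejected"
        )
    first, second = codes[:-1], codes[1:]
    valid = (first >= 0) & (second >= 0)
    dinuc_idx = np.where(valid, first * 4 + second, 0)
    series = table.values.T[dinuc_idx]  # (L-1, n_props)
    return series, valid


@dataclass(frozen=True)
class DACCVector:
    """Concatenated DAC then DCC components with their feature names."""

    values: np.ndarray
    names: tuple[str, ...]
    lag_max: int


def dacc_feature_names(table: PropertyTable, lag_max: int) -> list[str]:
    names = [
        f"dac_{u}_lag{lag}" for u in table.names for lag in range(1, lag_max + 1)
    ]
    names += [
        f"dcc_{u1}_{u2}_lag{lag}"
        for u1 in table.names
        for u2 in table.names
        if u1 != u2
        for lag in range(1, lag_max + 1)
    ]
    return names


def dacc(sequence: str, table: PropertyTable, lag_max: int = 2) -> DACCVector:
    """Dinucleotide auto-cross covariance encoding of one sequence.

    Components are ordered DAC first (property-major, lags ascending) then
    DCC over ordered property pairs; total dimension n_props^2 * lag_max.
    """
    L = len(sequence)
    if L < lag_max + 2:
        raise InputError(
            f"sequence length {L} too short for lag_max={lag_max}; need >= {lag_max + 2}"
        )
    series, valid = _property_series(sequence, table)
    nv = valid.sum()
    if nv == 0:
        raise InputError("no valid dinucleotide positions")
    means = (series * valid[:, None]).sum(axis=0) / nv
    centered = np.where(valid[:, None], series - means, 0.0)

    nprops = table.n_properties
    dac_vals = np.empty((nprops, lag_max))
    dcc_vals = np.empty((nprops, nprops, lag_max))
    for lag in range(1, lag_max + 1):
        a = centered[:-lag]  # (M-lag, nprops)
        b = centered[lag:]
        pair_valid = valid[:-lag] & valid[lag:]
        denom = pair_valid.sum()
        if denom == 0:
            dac_vals[:, lag - 1] = 0.0
            dcc_vals[:, :, lag - 1] = 0.0
            continue
        cross = a.T @ b / denom  # (nprops, nprops); invalid rows already zeroed
        dac_vals[:, lag - 1] = np.diag(cross)
        dcc_vals[:, :, lag - 1] = cross
    out = list(dac_vals.ravel())
    for i in range(nprops):
        for j in range(nprops):
            if i != j:
                out.extend(dcc_vals[i, j, :])
    return DACCVector(
        values=np.array(out),
        names=tuple(dacc_feature_names(table, lag_max)),
        lag_max=lag_max,
    )


@dataclass(frozen=True)
class SCPseDNCVector:
    """16 dinucleotide frequencies plus lambda*Lambda correlation factors."""

    values: np.ndarray
    names: tuple[str, ...]
    weight: float
    lambda_tier: int


def scpsednc_feature_names(table: PropertyTable, lambda_tier: int) -> list[str]:
    dim = 16 + lambda_tier * table.n_properties
    return [f"scpsednc_{k}" for k in range(1, dim + 1)]


def scpsednc(
    sequence: str,
    table: PropertyTable,
    lambda_tier: int = 2,
    weight: float = 0.1,
) -> SCPseDNCVector:
    """Series-correlation pseudo dinucleotide composition of one sequence.

    The correlation factors are ordered tier-major: for each distance
    m = 1..lambda, one factor per property. All components share the
    denominator (sum f + w * sum theta), so the vector sums to one.
    """
    L = len(sequence)
    if L == 0:
        raise InputError("empty sequence")
    if lambda_tier < 1:
        raise InputError("lambda_tier must be >= 1")
    if not 0 < weight <= 1:
        raise InputError("weight must be in (0, 1]")
    if lambda_tier >= L - 2:
        raise InputError(
            f"lambda_tier={lambda_tier} requires sequence length > {lambda_tier + 2}"
        )
    series, valid = _property_series(sequence, table)

    codes = encode_sequence(sequence)
    dinuc_idx = codes[:-1] * 4 + codes[1:]
    counts = np.bincount(dinuc_idx[valid], minlength=16).astype(float)
    if counts.sum() == 0:
        raise InputError("no valid dinucleotide positions")
    freqs = counts / counts.sum()

    nprops = table.n_properties
    thetas = np.empty(lambda_tier * nprops)
    for m in range(1, lambda_tier + 1):
        # literal summation range: pair (i, i+m) for i = 1..L-m-2 (1-based)
        hi = L - m - 2
        if hi < 1:
            raise InputError(f"sequence too short for correlation distance m={m}")
        a = series[:hi]
        b = series[m : m + hi]
        pair_valid = valid[:hi] & valid[m : m + hi]
        denom = pair_valid.sum()
        if denom == 0:
            thetas[(m - 1) * nprops : m * nprops] = 0.0
            continue
        prods = (a * b * pair_valid[:, None]).sum(axis=0) / denom
        thetas[(m - 1) * nprops : m * nprops] = prods

    denom = 1.0 + weight * thetas.sum()
    if denom <= 0:
        raise InputError("degenerate SCPseDNC denominator (w * sum(theta) <= -1)")
    values = np.concatenate([freqs / denom, weight * thetas / denom])
    return SCPseDNCVector(
        values=values,
        names=tuple(scpsednc_feature_names(table, lambda_tier)),
        weight=weight,
        lambda_tier=lambda_tier,
    )
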
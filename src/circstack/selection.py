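"""Feature-matrix assembly and mRMR feature selection.

The full encoder stack concatenates, per transcript and in fixed order:
64 trinucleotide frequencies, 4 ORF statistics, the DACC covariance
vector, the SCPseDNC vector, the summed Alu flank count and the
tandem-repeat frequency — 170 columns under defaults.

Selection uses minimum-redundancy-maximum-relevance (mRMR): features are
ranked greedily by mutual information with the class label, penalized by
their mean mutual information with the already-selected set, either as a
difference (MID) or a quotient (MIQ). Mutual information is the log2
plug-in estimate over discretized values; continuous features are
quantile-binned with edges fitted on the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from . import composition, physicochem, repeats
from .physicochem import PropertyTable
from .seqio import AnnotationIntervalSet, TranscriptRecord

LABEL_COLUMN = "label"


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class EncoderConfig:
    """Settings of the six feature groups; defaults give 170 columns."""

    k: int = 3
    lag_max: int = 2
    lambda_tier: int = 2
    weight: float = 0.1
    alu_windows: tuple[int, ...] = (1000, 2000)
    alu_per_window: bool = False  # emit alu_w<W> columns instead of alu_total
    tandem_min_period: int = 1
    tandem_max_period: int = 6
    tandem_min_copies: int = 3
    property_table: PropertyTable = field(default_factory=PropertyTable.default)

    def feature_names(self) -> list[str]:
        names = [f"kmer_{k}" for k in composition.KMER_NAMES_3]
        names += ["orf_length", "orf_coverage", "orf_avg_coverage", "orf_difference"]
        names += physicochem.dacc_feature_names(self.property_table, self.lag_max)
        names += physicochem.scpsednc_feature_names(self.property_table, self.lambda_tier)
        if self.alu_per_window:
            names += [f"alu_w{w}" for w in self.alu_windows]
        else:
            names += ["alu_total"]
        names += ["tandem_repeat_freq"]
        return names


@dataclass
class FeatureMatrix:
    """Transcripts x named feature columns, with optional binary labels."""

    values: np.ndarray
    feature_names: list[str]
    ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(set(self.feature_names)) != len(self.feature_names):
            raise InputError("feature names must be unique")
        if self.values.shape != (len(self.ids), len(self.feature_names)):
            raise InputError("matrix shape does not match ids/feature names")
        if np.isnan(self.values).any():
            raise InputError("feature matrix contains missing values")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def subset(self, names: Sequence[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(
            values=self.values[:, idx],
            feature_names=list(names),
            ids=list(self.ids),
            labels=None if self.labels is None else self.labels.copy(),
        )

    def rows(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values[mask],
            feature_names=list(self.feature_names),
            ids=[i for i, m in zip(self.ids, mask) if m],
            labels=None if self.labels is None else self.labels[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.ids, columns=self.feature_names)
        if self.labels is not None:
            df[LABEL_COLUMN] = self.labels
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="id")
        labels = None
        if LABEL_COLUMN in df.columns:
            labels = df.pop(LABEL_COLUMN).to_numpy(dtype=int)
        return cls(
            values=df.to_numpy(dtype=float),
            feature_names=list(df.columns),
            ids=[str(i) for i in df.index],
            labels=labels,
        )


def assemble_features(
    records: Sequence[TranscriptRecord],
    alu: AnnotationIntervalSet | None = None,
    config: EncoderConfig | None = None,
) -> FeatureMatrix:
    """Run all encoders on every transcript and stack rows into a matrix."""
    config = config or EncoderConfig()
    if alu is None:
        alu = AnnotationIntervalSet({})
    names = config.feature_names()
    rows = np.empty((len(records), len(names)))
    labels = [r.label for r in records]
    for i, rec in enumerate(records):
        try:
            parts = [composition.kmer_frequencies(rec.sequence, config.k).values]
            orf = composition.orf_features(rec.sequence)
            parts.append(np.array(list(orf.as_dict().values())))
            parts.append(
                physicochem.dacc(rec.sequence, config.property_table, config.lag_max).values
            )
            parts.append(
                physicochem.scpsednc(
                    rec.sequence, config.property_table, config.lambda_tier, config.weight
                ).values
            )
            counts = repeats.alu_flank_counts(rec.locus, alu, config.alu_windows)
            if config.alu_per_window:
                parts.append(np.array([float(counts[w]) for w in config.alu_windows]))
            else:
                parts.append(np.array([float(sum(counts.values()))]))
            parts.append(
                np.array(
                    [
                        repeats.tandem_repeat_frequency(
                            rec.sequence,
                            config.tandem_min_period,
                            config.tandem_max_period,
                            config.tandem_min_copies,
                        )
                    ]
                )
            )
        except ValueError as exc:
            raise InputError(f"encoding transcript {rec.id!r} failed: {exc}") from exc
        rows[i] = np.concatenate(parts)
    label_arr = (
        np.array([int(l) for l in labels]) if all(l is not None for l in labels) else None
    )
    return FeatureMatrix(values=rows, feature_names=names, ids=[r.id for r in records],
                         labels=label_arr)


# ---------------------------------------------------------------------------
# mutual information and discretization


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information in bits over two discrete series.

    I(X;Y) = sum_xy p(x,y) log2( p(x,y) / (p(x) p(y)) ), with 0 log 0 = 0.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise InputError("series must have equal length")
    if x.size < 2:
        raise InputError("need at least 2 observations")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny).astype(float)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))


@dataclass(frozen=True)
class Discretizer:
    """Quantile binning with edges fitted on one (training) sample."""

    edges: np.ndarray  # interior bin edges

    @classmethod
    def fit(cls, x: np.ndarray, bins: int = 10) -> "Discretizer":
        if bins < 2:
            raise InputError("bins must be >= 2")
        qs = np.linspace(0, 1, bins + 1)[1:-1]
        edges = np.unique(np.quantile(np.asarray(x, dtype=float), qs))
        return cls(edges=edges)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.edges, np.asarray(x, dtype=float), side="left")


def discretize(x: np.ndarray, bins: int = 10) -> np.ndarray:
    """Fit-and-transform quantile binning of one series (<= bins levels)."""
    return Discretizer.fit(x, bins).transform(x)


def discretize_matrix(
    train_values: np.ndarray, bins: int = 10, apply_to: np.ndarray | None = None
) -> np.ndarray:
    """Column-wise quantile binning; edges from the training values only."""
    target = train_values if apply_to is None else apply_to
    out = np.empty_like(target, dtype=np.int64)
    for j in range(train_values.shape[1]):
        out[:, j] = Discretizer.fit(train_values[:, j], bins).transform(target[:, j])
    return out


# ---------------------------------------------------------------------------
# mRMR


@dataclass
class MRMRRanking:
    order: list[int]
    feature_names: list[str]
    relevance: np.ndarray  # I(x_i; c) for every feature
    score_at_selection: list[float]
    criterion: Literal["MID", "MIQ"]

    def top(self, m: int) -> list[str]:
        return [self.feature_names[i] for i in self.order[:m]]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "rank": np.arange(1, len(self.order) + 1),
                "feature_name": [self.feature_names[i] for i in self.order],
                "relevance": self.relevance[self.order],
                "score": self.score_at_selection,
            }
        )
        df.to_csv(path, sep="\t", index=False)


def mrmr_rank(
    matrix: FeatureMatrix,
    m: int,
    criterion: Literal["MID", "MIQ"] = "MID",
    bins: int = 10,
) -> MRMRRanking:
    """Greedy mRMR ranking of ``m`` features against the class label.

    The first feature maximizes relevance I(x_i; c); each subsequent pick
    maximizes relevance minus (MID) or divided by (MIQ) the mean mutual
    information with the already-selected features. Ties break toward the
    lower column index.
    """
    if matrix.labels is None:
        raise InputError("labels required for mRMR")
    y = matrix.labels
    if len(np.unique(y)) < 2:
        raise InputError("labels contain a single class")
    p = matrix.n_features
    if not 1 <= m <= p:
        raise InputError(f"m={m} out of range [1, {p}]")
    disc = discretize_matrix(matrix.values, bins=bins)
    relevance = np.array([mutual_information(disc[:, j], y) for j in range(p)])

    selected: list[int] = []
    scores: list[float] = []
    remaining = list(range(p))
    redundancy_sum = np.zeros(p)
    eps = 1e-12
    while len(selected) < m:
        if not selected:
            crit = relevance.copy()
        else:
            mean_red = redundancy_sum / len(selected)
            if criterion == "MID":
                crit = relevance - mean_red
            else:
                crit = relevance / (mean_red + eps)
        best = max(remaining, key=lambda j: (crit[j], -j))
        selected.append(best)
        scores.append(float(crit[best]))
        remaining.remove(best)
        for j in remaining:
            redundancy_sum[j] += mutual_information(disc[:, j], disc[:, best])
    return MRMRRanking(
        order=selected,
        feature_names=list(matrix.feature_names),
        relevance=relevance,
        score_at_selection=scores,
        criterion=criterion,
    )


def sweep_dimensions(
    matrix: FeatureMatrix,
    model_builder: Callable[[FeatureMatrix, FeatureMatrix], dict[str, float]],
    dims: Sequence[int] = (30, 50, 70, 90, 110, 130, 150, 170),
    train_mask: np.ndarray | None = None,
    criterion: Literal["MID", "MIQ"] = "MID",
    bins: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate classifier metrics as a function of selection dimension.

    One mRMR ranking is computed on the training split and reused across
    all dimensions; ``model_builder(train, test)`` trains a model and
    returns its metric dict. Returns a table indexed by dimension.
    """
    dims = list(dims)
    if dims != sorted(dims):
        raise InputError("dims must be sorted ascending")
    if dims and dims[-1] > matrix.n_features:
        raise InputError(
            f"dimension {dims[-1]} exceeds feature count {matrix.n_features}"
        )
    if train_mask is None:
        from sklearn.model_selection import train_test_split

        idx = np.arange(len(matrix.ids))
        tr, _ = train_test_split(
            idx, test_size=0.25, stratify=matrix.labels, random_state=seed
        )
        train_mask = np.zeros(len(idx), dtype=bool)
        train_mask[tr] = True
    train = matrix.rows(train_mask)
    test = matrix.rows(~train_mask)
    ranking = mrmr_rank(train, m=max(dims), criterion=criterion, bins=bins)
    rows = []
    for d in dims:
        names = ranking.top(d)
        try:
            metrics = model_builder(train.subset(names), test.subset(names))
        except Exception as exc:  # re-raise with the dimension attached
            raise RuntimeError(f"model training failed at dimension {d}: {exc}") from exc
        rows.append({"dimension": d, **metrics})
    return pd.DataFrame(rows).set_index("dimension")
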
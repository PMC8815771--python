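"""Dataset containers, KEEL/CSV readers, standardization, synthetic data.

Binary imbalanced datasets are represented with the convention used
throughout the package: the minority (positive) class is labeled +1 and the
majority (negative) class is labeled -1.  Loaders enforce the convention by
relabeling the rarer class to +1, because every downstream formula
(membership values, sensitivity/specificity, G-mean) keys on
"positive = minority".
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class KeelFormatError(ValueError):
    """Raised when a KEEL .dat file cannot be parsed."""


class UnsupportedAttributeError(ValueError):
    """Raised for non-numeric input attributes (categorical encoding is out of scope)."""


@dataclass
class Dataset:
    """A labeled numeric feature matrix.

    Attributes
    ----------
    X : (n, p) float array, finite entries only.
    y : (n,) int array with values +1 (minority/positive) and -1 (majority).
    feature_names : list of p column identifiers.
    source : free-text provenance tag.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must match the number of rows of X")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains missing or non-finite values")
        if not np.all(np.isin(self.y, (-1, 1))):
            raise ValueError("labels must be +1 (minority) or -1 (majority)")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.X.shape[1])]
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must equal the number of columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class DatasetSummary:
    """Class counts and the imbalance ratio IR = n_maj / n_min."""

    n: int
    p: int
    n_min: int
    n_maj: int
    ir: float


def summarize(dataset: Dataset) -> DatasetSummary:
    """Count classes and compute the imbalance ratio n_maj / n_min."""
    n_min = int(np.sum(dataset.y == 1))
    n_maj = int(np.sum(dataset.y == -1))
    if n_min == 0 or n_maj == 0:
        raise ValueError("both classes must be present to summarize a dataset")
    return DatasetSummary(
        n=dataset.n, p=dataset.p, n_min=n_min, n_maj=n_maj, ir=n_maj / n_min
    )


def relabel_minority_positive(labels) -> np.ndarray:
    """Map arbitrary binary labels so the rarer one becomes +1.

    Ties are broken by preferring a label literally called "positive",
    else the first label in sorted order becomes +1.
    """
    labels = np.asarray(labels)
    values, counts = np.unique(labels, return_counts=True)
    if len(values) != 2:
        raise ValueError(f"expected exactly 2 class labels, got {len(values)}")
    if counts[0] != counts[1]:
        pos = values[np.argmin(counts)]
    else:
        named = [v for v in values if str(v).strip().lower() == "positive"]
        pos = named[0] if named else values[0]
    return np.where(labels == pos, 1, -1)


# --------------------------------------------------------------------------
# KEEL .dat dialect
# --------------------------------------------------------------------------

def _parse_keel_attribute(line: str):
    body = line[len("@attribute"):].strip()
    if "{" in body:
        name = body[: body.index("{")].strip()
        values = [v.strip() for v in body[body.index("{") + 1 : body.rindex("}")].split(",")]
        return name, "nominal", values
    parts = body.split()
    name = parts[0]
    kind = parts[1].lower() if len(parts) > 1 else "real"
    # strip range annotations like real[0.0,10.0]
    kind = kind.split("[")[0]
    return name, kind, None


def read_keel(text_or_path) -> Dataset:
    """Parse a KEEL ``.dat`` file (header + comma-separated body).

    The dialect: ``@relation``, ``@attribute`` lines (numeric or a nominal
    class with exactly two values), optional ``@inputs``/``@outputs``, then
    ``@data`` followed by CSV rows.  Blank lines and ``%`` comments are
    ignored; class values compare case-insensitively.  The rarer class is
    relabeled +1; if a class named "positive" is actually the commoner one a
    warning is emitted.
    """
    if isinstance(text_or_path, (str, os.PathLike)) and "\n" not in str(text_or_path):
        with open(text_or_path) as fh:
            text = fh.read()
        source = str(text_or_path)
    else:
        text = text_or_path.read() if hasattr(text_or_path, "read") else str(text_or_path)
        source = "<inline>"

    attributes: list[tuple[str, str, list[str] | None]] = []
    output_name: str | None = None
    data_rows: list[list[str]] = []
    in_data = False
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if in_data:
            data_rows.append([tok.strip() for tok in line.split(",")])
        elif low.startswith("@attribute"):
            attributes.append(_parse_keel_attribute(line))
        elif low.startswith("@outputs") or low.startswith("@output"):
            names = line.split(None, 1)[1] if len(line.split(None, 1)) > 1 else ""
            output_name = names.split(",")[0].strip()
        elif low.startswith("@data"):
            in_data = True
        # @relation / @inputs / @input carry no information we need
    if not in_data:
        raise KeelFormatError("missing @data section")
    if not attributes:
        raise KeelFormatError("no @attribute declarations found")

    names = [a[0] for a in attributes]
    if output_name is not None:
        matches = [i for i, n in enumerate(names) if n.lower() == output_name.lower()]
        class_idx = matches[0] if matches else len(attributes) - 1
    else:
        class_idx = len(attributes) - 1
    cname, ckind, cvalues = attributes[class_idx]
    if ckind != "nominal":
        raise KeelFormatError(f"class attribute {cname!r} must be nominal")
    if cvalues is not None and len(cvalues) != 2:
        raise KeelFormatError(f"class attribute {cname!r} must have exactly 2 values")

    feature_names = []
    for i, (name, kind, _values) in enumerate(attributes):
        if i == class_idx:
            continue
        if kind not in ("real", "integer", "numeric"):
            raise UnsupportedAttributeError(
                f"input attribute {name!r} has unsupported type {kind!r}"
            )
        feature_names.append(name)

    n_cols = len(attributes)
    X = np.empty((len(data_rows), n_cols - 1))
    raw_labels = []
    for r, row in enumerate(data_rows):
        if len(row) != n_cols:
            raise KeelFormatError(
                f"data row {r} has {len(row)} fields, expected {n_cols}"
            )
        c = 0
        for i, tok in enumerate(row):
            if i == class_idx:
                raw_labels.append(tok.strip().lower())
            else:
                try:
                    X[r, c] = float(tok)
                except ValueError as exc:
                    raise UnsupportedAttributeError(
                        f"non-numeric value {tok!r} in attribute {names[i]!r}"
                    ) from exc
                c += 1
    raw_labels = np.asarray(raw_labels)
    observed = np.unique(raw_labels)
    if len(observed) > 2:
        raise KeelFormatError(f"more than 2 class values in data: {list(observed)}")
    y = relabel_minority_positive(raw_labels)
    counts = {v: int(np.sum(raw_labels == v)) for v in observed}
    if "positive" in counts and counts["positive"] > min(counts.values()):
        warnings.warn(
            "class named 'positive' is the larger class; relabeled by count so the "
            "minority class is +1",
            stacklevel=2,
        )
    return Dataset(X=X, y=y, feature_names=feature_names, source=source)


def write_keel(dataset: Dataset, path_or_buf=None, relation: str = "dataset") -> str | None:
    """Serialize a Dataset to KEEL text; +1 rows get class "positive"."""
    buf = io.StringIO()
    buf.write(f"@relation {relation}\n")
    for name in dataset.feature_names:
        buf.write(f"@attribute {name} real\n")
    buf.write("@attribute Class {positive, negative}\n")
    buf.write("@inputs " + ", ".join(dataset.feature_names) + "\n")
    buf.write("@outputs Class\n@data\n")
    for row, label in zip(dataset.X, dataset.y):
        cells = [repr(float(v)) for v in row]
        cells.append("positive" if label == 1 else "negative")
        buf.write(", ".join(cells) + "\n")
    text = buf.getvalue()
    if path_or_buf is None:
        return text
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)
    return None


def read_table(path_or_buf, label_column: str | None = None, sep=None) -> Dataset:
    """Read a delimited table; ``label_column`` defaults to the last column."""
    df = pd.read_csv(path_or_buf, sep=sep, engine="python")
    if label_column is None:
        label_column = df.columns[-1]
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not in table")
    y = relabel_minority_positive(df[label_column].to_numpy())
    features = df.drop(columns=[label_column])
    X = features.to_numpy(dtype=float)
    source = str(path_or_buf) if isinstance(path_or_buf, (str, os.PathLike)) else "<buffer>"
    return Dataset(X=X, y=y, feature_names=list(features.columns), source=source)


# --------------------------------------------------------------------------
# Standardization
# --------------------------------------------------------------------------

def standardize(train_X: np.ndarray, other_X: np.ndarray | None = None):
    """Z-score columns with training-fold statistics.

    Returns ``(train_Z, other_Z, mean, scale)``.  Constant training columns
    get scale 1 (centered only).  ``other_X`` is transformed with the
    TRAINING mean and standard deviation, never its own.
    """
    train_X = np.asarray(train_X, dtype=float)
    if train_X.shape[0] < 2:
        raise ValueError("need at least 2 training rows to standardize")
    mean = train_X.mean(axis=0)
    scale = train_X.std(axis=0, ddof=0)
    scale = np.where(scale == 0.0, 1.0, scale)
    train_Z = (train_X - mean) / scale
    other_Z = None if other_X is None else (np.asarray(other_X, dtype=float) - mean) / scale
    return train_Z, other_Z, mean, scale


# --------------------------------------------------------------------------
# Synthetic imbalanced data
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a two-class Gaussian-mixture dataset.

    ``class_separation`` is the distance between the two class centroids;
    ``within_class_spread`` is the isotropic standard deviation of each
    sub-cluster.  ``clusters_per_class`` > 1 scatters sub-cluster centers
    around each centroid to mimic irregular (multi-modal) class shapes.
    """

    p: int = 5
    n_maj: int = 200
    ir: float = 10.0
    clusters_per_class: int = 1
    class_separation: float = 3.0
    within_class_spread: float = 1.0
    label_noise_frac: float = 0.0
    seed: int = 0


def make_synthetic(spec: SyntheticSpec) -> Dataset:
    """Draw an imbalanced Gaussian-mixture dataset; bit-reproducible per seed.

    Class counts are exact before label noise: ``n_min = round(n_maj / ir)``.
    ``label_noise_frac`` then flips that fraction of labels uniformly at
    random.
    """
    if spec.ir < 1:
        raise ValueError("ir must be >= 1 (majority at least as large as minority)")
    if not 0 <= spec.label_noise_frac < 1:
        raise ValueError("label_noise_frac must be in [0, 1)")
    n_min = int(round(spec.n_maj / spec.ir))
    if n_min < 2:
        raise ValueError(f"ir={spec.ir} with n_maj={spec.n_maj} yields n_min={n_min} < 2")
    rng = np.random.default_rng(spec.seed)

    direction = rng.normal(size=spec.p)
    direction /= np.linalg.norm(direction)
    centroids = {-1: np.zeros(spec.p), 1: spec.class_separation * direction}

    rows, labels = [], []
    for label, count in ((-1, spec.n_maj), (1, n_min)):
        c = spec.clusters_per_class
        if c > 1:
            offsets = rng.normal(scale=1.5 * spec.within_class_spread, size=(c, spec.p))
        else:
            offsets = np.zeros((1, spec.p))
        centers = centroids[label] + offsets
        assignment = rng.integers(0, c, size=count)
        noise = rng.normal(scale=spec.within_class_spread, size=(count, spec.p))
        rows.append(centers[assignment] + noise)
        labels.append(np.full(count, label))
    X = np.vstack(rows)
    y = np.concatenate(labels)

    if spec.label_noise_frac > 0:
        n_flip = int(round(spec.label_noise_frac * len(y)))
        flip = rng.choice(len(y), size=n_flip, replace=False)
        y = y.copy()
        y[flip] *= -1

    return Dataset(X=X, y=y, source=f"synthetic(seed={spec.seed})")
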
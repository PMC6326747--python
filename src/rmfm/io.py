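"""Connectivity matrices and ROI tables.

Containers for structural connectivity (SC), functional connectivity (FC)
and regional BOLD time series, plus the group-level SC consensus averaging
rule, Pearson FC computation, and the upper-triangle vectorization used to
compare FC matrices while ignoring the diagonal and duplicated entries.

Matrices are exchanged as plain delimited text (CSV/TSV), optionally with a
header row of ROI labels; nothing here needs a binary format at the scale of
a cortical parcellation (n of order 100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SCMatrix",
    "FCMatrix",
    "ROITimeSeries",
    "group_average_sc",
    "compute_fc",
    "vectorize_upper",
    "unvectorize_upper",
    "fc_agreement",
    "read_matrix",
    "write_matrix",
    "read_roi_table",
]

_SYMMETRY_TOL = 1e-8


def _default_labels(n: int) -> list[str]:
    return [f"ROI{i + 1:03d}" for i in range(n)]


def _symmetrize(values: np.ndarray, what: str) -> np.ndarray:
    asym = np.abs(values - values.T).max() if values.size else 0.0
    if asym > _SYMMETRY_TOL:
        warnings.warn(
            f"{what} asymmetric beyond tolerance (max |A-A'| = {asym:.3g}); "
            "symmetrizing by averaging with the transpose",
            stacklevel=3,
        )
    return 0.5 * (values + values.T)


@dataclass
class SCMatrix:
    """Structural coupling matrix C_ij (dimensionless after scaling).

    Symmetric, nonnegative, zero diagonal. Group-averaged matrices are
    rescaled so the maximum entry equals ``scale_max`` (0.2 by default),
    which keeps the inter-regional drive in the mean-field model in the
    regime used throughout this literature.
    """

    values: np.ndarray
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"SC matrix must be square, got shape {self.values.shape}")
        if np.any(self.values < 0):
            raise ValueError("SC matrix entries must be nonnegative")
        self.values = _symmetrize(self.values, "SC matrix")
        np.fill_diagonal(self.values, 0.0)
        if not self.roi_labels:
            self.roi_labels = _default_labels(self.n)
        if len(self.roi_labels) != self.n:
            raise ValueError("roi_labels length does not match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class FCMatrix:
    """Functional connectivity: Pearson correlations between regional signals."""

    values: np.ndarray
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"FC matrix must be square, got shape {self.values.shape}")
        self.values = _symmetrize(self.values, "FC matrix")
        if np.any(np.abs(self.values) > 1 + 1e-9):
            raise ValueError("FC entries must lie in [-1, 1]")
        np.clip(self.values, -1.0, 1.0, out=self.values)
        np.fill_diagonal(self.values, 1.0)
        if not self.roi_labels:
            self.roi_labels = _default_labels(self.n)
        if len(self.roi_labels) != self.n:
            raise ValueError("roi_labels length does not match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class ROITimeSeries:
    """Regional BOLD signals: ``values[i, t]`` is region i at frame t.

    ``tr`` is the sampling period in seconds.
    """

    values: np.ndarray
    tr: float
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a regions x frames matrix")
        if self.values.shape[1] < 2:
            raise ValueError("need at least two frames per region")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not self.roi_labels:
            self.roi_labels = _default_labels(self.n)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def group_average_sc(
    subject_scs: Sequence[np.ndarray],
    consensus_fraction: float = 0.5,
    scale_max: float = 0.2,
    roi_labels: Sequence[str] | None = None,
) -> SCMatrix:
    """Consensus-average subject streamline-count matrices into a group SC.

    An entry is zeroed when *fewer than* ``consensus_fraction`` of subjects
    have any streamlines there (a fraction exactly at the threshold is kept);
    surviving entries are averaged over the subjects with nonzero counts
    only, so sparsely-present connections are not diluted toward zero. The
    result is rescaled so its maximum equals ``scale_max``.
    """
    if len(subject_scs) == 0:
        raise ValueError("need at least one subject matrix")
    mats = [np.asarray(m, dtype=float) for m in subject_scs]
    shape = mats[0].shape
    if shape[0] != shape[1]:
        raise ValueError(f"subject matrices must be square, got {shape}")
    for k, m in enumerate(mats):
        if m.shape != shape:
            raise ValueError(f"subject {k} has shape {m.shape}, expected {shape}")
        if np.any(m < 0):
            raise ValueError(f"subject {k} has negative streamline counts")
    stack = np.stack(mats)
    nonzero = stack > 0
    frac = nonzero.mean(axis=0)
    n_nonzero = nonzero.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_nonzero = np.where(
            n_nonzero > 0, stack.sum(axis=0) / np.maximum(n_nonzero, 1), 0.0
        )
    out = np.where(frac >= consensus_fraction, mean_nonzero, 0.0)
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 0.0)
    peak = out.max()
    if peak <= 0:
        raise ValueError(
            "consensus matrix is identically zero; cannot rescale to "
            f"scale_max={scale_max}"
        )
    out *= scale_max / peak
    return SCMatrix(out, list(roi_labels) if roi_labels else [])


def compute_fc(ts: ROITimeSeries) -> FCMatrix:
    """Pearson correlation between every pair of regional time series."""
    sd = ts.values.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        names = ", ".join(ts.roi_labels[i] for i in flat[:5])
        raise ValueError(f"zero-variance time series in region(s): {names}")
    fc = np.corrcoef(ts.values)
    return FCMatrix(fc, list(ts.roi_labels))


def vectorize_upper(m: np.ndarray) -> np.ndarray:
    """Strict upper-triangle entries in row-major (i<j, sorted by (i, j)) order.

    For an n x n matrix the result has length n(n-1)/2; this fixed ordering
    makes vectors comparable across runs and implementations.
    """
    m = np.asarray(m)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def unvectorize_upper(v: np.ndarray, n: int, diagonal: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize_upper` onto a symmetric matrix."""
    v = np.asarray(v, dtype=float)
    if v.size != n * (n - 1) // 2:
        raise ValueError(f"vector length {v.size} does not match n={n}")
    out = np.full((n, n), float(diagonal))
    iu = np.triu_indices(n, k=1)
    out[iu] = v
    out[(iu[1], iu[0])] = v
    return out


def fc_agreement(a: FCMatrix | np.ndarray, b: FCMatrix | np.ndarray) -> float:
    """Pearson correlation of two matrices' strict upper triangles.

    The diagonal and the duplicated lower-triangle entries carry no
    information and are ignored.
    """
    va = vectorize_upper(a.values if isinstance(a, (FCMatrix, SCMatrix)) else a)
    vb = vectorize_upper(b.values if isinstance(b, (FCMatrix, SCMatrix)) else b)
    if va.size != vb.size:
        raise ValueError("matrices have different sizes")
    if va.size < 3:
        raise ValueError("need at least 3 off-diagonal entries (n >= 3)")
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("agreement undefined: an upper triangle has zero variance")
    return float(np.corrcoef(va, vb)[0, 1])


def read_matrix(path, cls=None):
    """Read a square delimited matrix, auto-detecting a header row of labels."""
    first = pd.read_csv(path, sep=None, engine="python", header=None, nrows=1)
    has_header = first.iloc[0].apply(
        lambda x: isinstance(x, str) and not _is_number(x)
    ).any()
    if has_header:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        labels = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=float)
    else:
        df = pd.read_csv(path, sep=None, engine="python", header=None)
        labels = []
        values = df.to_numpy(dtype=float)
    if cls is None:
        return values, labels
    return cls(values, labels)


def _is_number(x: str) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def write_matrix(path, m, labels: Sequence[str] | None = None) -> None:
    values = m.values if hasattr(m, "values") else np.asarray(m)
    if labels is None:
        labels = getattr(m, "roi_labels", None)
    if labels:
        pd.DataFrame(values, index=list(labels), columns=list(labels)).to_csv(path)
    else:
        pd.DataFrame(values).to_csv(path, header=False, index=False)


def read_roi_table(path) -> pd.Series:
    """Two-column (label, value) table -> Series indexed by ROI label."""
    df = pd.read_csv(path, sep=None, engine="python", header=None)
    if df.shape[1] != 2:
        raise ValueError(f"expected a two-column ROI table, got {df.shape[1]} columns")
    if not _is_number(str(df.iloc[0, 1])):
        df = df.iloc[1:]
    return pd.Series(df.iloc[:, 1].astype(float).values, index=df.iloc[:, 0].astype(str))
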
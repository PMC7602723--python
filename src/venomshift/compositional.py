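"""Compositional algebra for venom peak tables.

HPLC peak relative abundances carry only relative information: each venom
sample is a point on the simplex, and all downstream statistics operate in
Aitchison geometry.  This module provides closure, multiplicative zero
replacement, the centered and isometric log-ratio transforms, Aitchison
distances, and the distance-from-juvenile-baseline series that the
trajectory models consume.

The log-ratio arithmetic itself is delegated to
:mod:`skbio.stats.composition`; this module adds the validation contracts,
the peak-table container, and the baseline-series construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import helmert
from skbio.stats.composition import clr as _skbio_clr
from skbio.stats.composition import multi_replace as _skbio_multi_replace

from .errors import (
    DegenerateSampleError,
    InsufficientDataError,
    ParameterError,
    ValidationError,
)

__all__ = [
    "PeakTable",
    "BaselineSeries",
    "close",
    "replace_zeros",
    "clr",
    "ilr",
    "ilr_basis",
    "aitchison_distance",
    "baseline_distance_series",
]

_CLOSURE_TOL = 1e-9


@dataclass
class PeakTable:
    """One individual's longitudinal venom composition matrix.

    Rows of ``abundance`` are samples (in collection order), columns are
    HPLC peaks called for this individual.  ``sample_days`` are integer
    days since the first sample.  ``svl`` is snout–vent length in cm and
    may contain NaN where no measurement was taken.
    """

    snake_id: str
    species: str
    sample_days: np.ndarray
    svl: np.ndarray
    peak_ids: list[str]
    retention_times: np.ndarray
    abundance: np.ndarray
    sample_ids: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.sample_days = np.asarray(self.sample_days, dtype=int)
        self.svl = np.asarray(self.svl, dtype=float)
        self.retention_times = np.asarray(self.retention_times, dtype=float)
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.sample_ids is None:
            self.sample_ids = [f"{self.snake_id}_s{i}" for i in range(self.n_samples)]

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.abundance.shape[1]

    def validate(self, require_closed: bool = True, min_samples: int = 1) -> None:
        """Check the structural invariants; raise ``ValidationError`` on failure."""
        a = self.abundance
        if a.ndim != 2:
            raise ValidationError("abundance must be a 2-D samples x peaks matrix")
        if a.shape != (len(self.sample_days), len(self.peak_ids)):
            raise ValidationError(
                f"abundance shape {a.shape} inconsistent with "
                f"{len(self.sample_days)} samples / {len(self.peak_ids)} peaks"
            )
        if len(self.retention_times) != self.n_peaks:
            raise ValidationError("one retention time per peak required")
        if np.any(a < 0):
            raise ValidationError("abundance entries must be nonnegative")
        if np.any(np.diff(self.sample_days) <= 0):
            raise ValidationError("sample_days must be strictly increasing")
        if np.any((self.retention_times < 0) | (self.retention_times > 150)):
            raise ValidationError("retention times must lie within [0, 150] minutes")
        if require_closed and np.any(np.abs(a.sum(axis=1) - 1.0) > _CLOSURE_TOL):
            raise ValidationError("abundance rows must sum to 1 (apply close() first)")
        if self.n_samples < min_samples:
            raise InsufficientDataError(
                f"{self.snake_id}: {self.n_samples} samples < required {min_samples}"
            )

    def closed(self) -> "PeakTable":
        """Return a copy with rows closed to proportions."""
        return self.with_abundance(close(self.abundance))

    def with_abundance(self, abundance: np.ndarray) -> "PeakTable":
        return PeakTable(
            snake_id=self.snake_id,
            species=self.species,
            sample_days=self.sample_days.copy(),
            svl=self.svl.copy(),
            peak_ids=list(self.peak_ids),
            retention_times=self.retention_times.copy(),
            abundance=np.asarray(abundance, dtype=float),
            sample_ids=list(self.sample_ids),
        )


@dataclass
class BaselineSeries:
    """Aitchison distance of every sample from the juvenile baseline."""

    baseline: np.ndarray
    distances: np.ndarray
    scaled_distances: np.ndarray | None
    days: np.ndarray
    sample_ids: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        ids = self.sample_ids or [f"s{i}" for i in range(len(self.days))]
        return pd.DataFrame(
            {
                "sample_id": ids,
                "day": self.days,
                "distance": self.distances,
                "scaled_distance": (
                    self.scaled_distances
                    if self.scaled_distances is not None
                    else np.full(len(self.days), np.nan)
                ),
            }
        )


def close(matrix: np.ndarray) -> np.ndarray:
    """Close rows of a nonnegative matrix (or a single vector) to sum to 1."""
    m = np.asarray(matrix, dtype=float)
    vector_in = m.ndim == 1
    m = np.atleast_2d(m)
    if np.any(m < 0):
        raise ValidationError("closure requires nonnegative entries")
    sums = m.sum(axis=1)
    zero_rows = np.flatnonzero(sums <= 0)
    if zero_rows.size:
        raise DegenerateSampleError(
            f"row(s) {zero_rows.tolist()} have zero total abundance"
        )
    out = m / sums[:, None]
    return out[0] if vector_in else out


def replace_zeros(matrix: np.ndarray, delta: float = 6.5e-4) -> np.ndarray:
    """Multiplicative zero replacement on a closed matrix.

    Zeros become ``delta``; nonzero entries in a row with ``Z`` zeros are
    multiplied by ``1 - Z*delta`` so the row stays closed and within-row
    ratios among nonzero parts are preserved.  The default delta is 0.65x
    the 0.1% minor-peak reporting threshold.
    """
    m = np.atleast_2d(np.asarray(matrix, dtype=float))
    vector_in = np.asarray(matrix).ndim == 1
    if np.any(np.abs(m.sum(axis=1) - 1.0) > _CLOSURE_TOL):
        raise ValidationError("replace_zeros expects a closed matrix")
    positive = m[m > 0]
    if positive.size and delta >= positive.min():
        raise ParameterError(
            f"delta={delta} must be smaller than the smallest positive entry "
            f"({positive.min():.3g})"
        )
    if not 0 < delta < 1:
        raise ParameterError("delta must lie in (0, 1)")
    out = np.atleast_2d(_skbio_multi_replace(m, delta=delta))
    return out[0] if vector_in else out


def _validate_positive_composition(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValidationError("composition parts must be strictly positive")
    return x


def clr(x: np.ndarray) -> np.ndarray:
    """Centered log-ratio transform; rows map to the zero-sum hyperplane."""
    return _skbio_clr(_validate_positive_composition(x))


def ilr_basis(n_parts: int) -> np.ndarray:
    """Default orthonormal (Helmert-type) ilr contrast basis, shape (D-1, D)."""
    if n_parts < 2:
        raise ParameterError("ilr basis needs at least 2 parts")
    return helmert(n_parts)


def ilr(x: np.ndarray, basis: np.ndarray | None = None) -> np.ndarray:
    """Isometric log-ratio coordinates: ``basis @ clr(x)`` per row.

    Any orthonormal basis of the clr hyperplane yields the same geometry;
    the fixed Helmert default gives reproducible coordinates.
    """
    x = _validate_positive_composition(x)
    d = x.shape[-1]
    if basis is None:
        basis = ilr_basis(d)
    basis = np.asarray(basis, dtype=float)
    if basis.shape != (d - 1, d):
        raise ParameterError(f"basis must have shape {(d - 1, d)}, got {basis.shape}")
    if not np.allclose(basis @ basis.T, np.eye(d - 1), atol=1e-8):
        raise ParameterError("basis rows must be orthonormal")
    if not np.allclose(basis @ np.ones(d), 0.0, atol=1e-8):
        raise ParameterError("basis rows must be orthogonal to the all-ones vector")
    return clr(x) @ basis.T


def aitchison_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Aitchison distance: Euclidean distance between clr images."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"shape mismatch: {x.shape} vs {y.shape}")
    return float(np.linalg.norm(clr(close(x)) - clr(close(y))))


def geometric_mean_composition(matrix: np.ndarray) -> np.ndarray:
    """Closed component-wise geometric mean — the Frechet mean in Aitchison
    geometry, consistent with the clr metric used for distances."""
    m = _validate_positive_composition(np.atleast_2d(matrix))
    return close(np.exp(np.log(m).mean(axis=0)))


def arithmetic_mean_composition(matrix: np.ndarray) -> np.ndarray:
    m = np.atleast_2d(np.asarray(matrix, dtype=float))
    return close(m.mean(axis=0))


def baseline_distance_series(
    table: PeakTable,
    n_baseline: int = 3,
    scale: bool = True,
    mean: str = "geometric",
) -> BaselineSeries:
    """Distance of every sample from the mean of the earliest juvenile samples.

    The baseline is the mean composition of the ``n_baseline`` earliest
    samples — an average of early composition rather than a potentially
    noisy single first sample.  ``mean`` selects the compositional
    (geometric, default) or arithmetic average.  With ``scale``, distances
    are divided by their own mean so trajectories from different
    individuals share a scale.
    """
    table.validate(require_closed=True)
    if table.n_samples < n_baseline + 1:
        raise InsufficientDataError(
            f"{table.snake_id}: need at least {n_baseline + 1} samples, "
            f"have {table.n_samples}"
        )
    a = table.abundance
    if np.any(a <= 0):
        raise ValidationError("zeros present: apply replace_zeros before distances")
    base_rows = a[:n_baseline]
    if mean == "geometric":
        baseline = geometric_mean_composition(base_rows)
    elif mean == "arithmetic":
        baseline = arithmetic_mean_composition(base_rows)
    else:
        raise ParameterError(f"unknown mean kind {mean!r}")
    clr_samples = clr(a)
    clr_base = clr(baseline)
    distances = np.linalg.norm(clr_samples - clr_base, axis=1)
    if scale:
        m = distances.mean()
        # all-identical samples give a zero mean distance; scaling is undefined
        scaled = distances / m if m > 0 else np.zeros_like(distances)
    else:
        scaled = None
    return BaselineSeries(
        baseline=baseline,
        distances=distances,
        scaled_distances=scaled,
        days=table.sample_days.copy(),
        sample_ids=list(table.sample_ids),
    )
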
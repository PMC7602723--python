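"""Shared venom space: retention-time binning and NMDS ordination.

HPLC peaks are called independently within each individual, so peak
columns are not comparable between snakes.  Summing peak areas into fixed
retention-time windows (R1: 10-20 min ... R11: 110-125 min) yields a
common 11-part composition for every sample, and non-metric
multidimensional scaling of the pairwise Aitchison distances projects all
samples from all individuals into one low-dimensional phenotype space.

The SMACOF/isotonic-regression engine is scikit-learn's; this module adds
multi-start bookkeeping, Kruskal stress-1 reporting, validation, and the
binning itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.manifold import smacof

from .compositional import PeakTable, clr, close, replace_zeros
from .errors import ParameterError, ValidationError

__all__ = [
    "RETENTION_WINDOWS",
    "BinnedTable",
    "NmdsResult",
    "bin_retention_windows",
    "nmds",
    "pairwise_aitchison",
]

# contiguous half-open windows [lo, hi); the last is closed at 125 min
RETENTION_WINDOWS: list[tuple[str, float, float]] = [
    ("R1", 10, 20),
    ("R2", 20, 30),
    ("R3", 30, 40),
    ("R4", 40, 50),
    ("R5", 50, 60),
    ("R6", 60, 70),
    ("R7", 70, 80),
    ("R8", 80, 90),
    ("R9", 90, 100),
    ("R10", 100, 110),
    ("R11", 110, 125),
]


@dataclass
class BinnedTable:
    window_labels: list[str]
    window_bounds: list[tuple[float, float]]
    binned_abundance: np.ndarray  # samples x 11, rows closed
    snake_ids: list[str]
    sample_ids: list[str]
    sample_days: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.binned_abundance, columns=self.window_labels)
        df.insert(0, "snake_id", self.snake_ids)
        df.insert(1, "sample_id", self.sample_ids)
        df.insert(2, "day", self.sample_days)
        return df


@dataclass
class NmdsResult:
    coords: np.ndarray
    stress: float  # Kruskal stress-1
    n_starts: int
    seed: int | None
    converged: bool


def _window_index(rt: float, peak_id: str) -> int:
    if rt < RETENTION_WINDOWS[0][1] or rt > RETENTION_WINDOWS[-1][2]:
        raise ParameterError(
            f"peak {peak_id!r}: retention time {rt} min outside "
            f"[{RETENTION_WINDOWS[0][1]}, {RETENTION_WINDOWS[-1][2]}]"
        )
    for i, (_, lo, hi) in enumerate(RETENTION_WINDOWS):
        if lo <= rt < hi:
            return i
    return len(RETENTION_WINDOWS) - 1  # rt == 125 exactly


def bin_retention_windows(tables: Iterable[PeakTable]) -> BinnedTable:
    """Sum each sample's peak abundances into the eleven shared windows.

    Rows are re-closed afterwards; binned rows depend only on each
    sample's own composition, never on other samples or peak labels.
    """
    rows, snakes, ids, days = [], [], [], []
    n_win = len(RETENTION_WINDOWS)
    for table in tables:
        table.validate(require_closed=False)
        win_idx = [
            _window_index(rt, pid)
            for rt, pid in zip(table.retention_times, table.peak_ids)
        ]
        binned = np.zeros((table.n_samples, n_win))
        for j, w in enumerate(win_idx):
            binned[:, w] += table.abundance[:, j]
        rows.append(binned)
        snakes.extend([table.snake_id] * table.n_samples)
        ids.extend(table.sample_ids)
        days.extend(table.sample_days.tolist())
    if not rows:
        raise ParameterError("no peak tables supplied")
    return BinnedTable(
        window_labels=[w[0] for w in RETENTION_WINDOWS],
        window_bounds=[(w[1], w[2]) for w in RETENTION_WINDOWS],
        binned_abundance=close(np.vstack(rows)),
        snake_ids=snakes,
        sample_ids=ids,
        sample_days=np.asarray(days),
    )


def pairwise_aitchison(compositions: np.ndarray, delta: float = 6.5e-4) -> np.ndarray:
    """Pairwise Aitchison distance matrix of closed composition rows.

    Empty parts are handled by the standard multiplicative zero
    replacement before the clr transform.
    """
    comps = close(np.asarray(compositions, dtype=float))
    if np.any(comps == 0):
        comps = replace_zeros(comps, delta=delta)
    z = clr(comps)
    diff = z[:, None, :] - z[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def kruskal_stress(dmat: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against target dissimilarities,
    with the monotone (primary-ties) regression of configuration distances
    on dissimilarity ranks."""
    from scipy.spatial.distance import pdist, squareform
    from sklearn.isotonic import IsotonicRegression

    d_target = squareform(dmat, checks=False)
    d_conf = pdist(coords)
    order = np.argsort(d_target, kind="stable")
    iso = IsotonicRegression()
    fitted = np.empty_like(d_conf)
    fitted[order] = iso.fit_transform(d_target[order], d_conf[order])
    denom = float((d_conf**2).sum())
    return float(np.sqrt(((d_conf - fitted) ** 2).sum() / denom))


def nmds(
    distance_matrix: np.ndarray,
    dims: int = 2,
    n_starts: int = 20,
    seed: int | None = None,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> NmdsResult:
    """Non-metric MDS by SMACOF with isotonic regression, best of
    ``n_starts`` random initializations, coordinates centered at the
    origin; stress is Kruskal's stress-1."""
    d = np.asarray(distance_matrix, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape != (n, n):
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-8):
        raise ValidationError("distance matrix must have a zero diagonal")
    if np.all(d == 0):
        raise ValidationError("all-zero distances: configuration is degenerate")
    if n < dims + 2:
        raise ParameterError(f"need >= {dims + 2} points for {dims}-D NMDS")

    rng = np.random.default_rng(seed)
    best_coords, best_stress = None, np.inf
    for _ in range(n_starts):
        coords, stress = smacof(
            d,
            metric=False,
            n_components=dims,
            n_init=1,
            max_iter=max_iter,
            eps=tol,
            random_state=int(rng.integers(0, 2**31 - 1)),
            normalized_stress=True,
        )
        if stress < best_stress:
            best_coords, best_stress = coords, stress
    best_coords = best_coords - best_coords.mean(axis=0)
    return NmdsResult(
        coords=best_coords,
        stress=float(best_stress),
        n_starts=n_starts,
        seed=seed,
        converged=np.isfinite(best_stress),
    )


def window_centroids(
    binned: BinnedTable, coords: np.ndarray
) -> pd.DataFrame:
    """Abundance-weighted position of each retention window in the
    ordination — the annotation used to orient samples in venom space."""
    w = close(binned.binned_abundance)
    weights = w / w.sum(axis=0)
    cent = weights.T @ coords
    return pd.DataFrame(
        cent, index=binned.window_labels, columns=[f"axis{i+1}" for i in range(coords.shape[1])]
    )
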
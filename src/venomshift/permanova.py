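"""Permutational MANOVA with a continuous predictor.

Tests whether a multivariate compositional response (ilr coordinates of
venom composition) changes with a continuous covariate such as day of
study or body size.  Because ilr coordinates are Euclidean, the
least-squares projection formulation used here is exactly equivalent to
the Gower-centered distance-matrix formulation of the classical
distance-based PERMANOVA; the equivalence is exercised in the test suite.

Significance comes from permuting the predictor: the p-value is the
proportion of permuted pseudo-F statistics at least as large as the
observed one, with the +1 small-sample correction for sampled
permutations.  For very small series (n <= 7) all orderings are
enumerated and the exact tail proportion is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _iter_permutations

import numpy as np

from .compositional import PeakTable, ilr
from .errors import DegenerateDesignError, InsufficientDataError

__all__ = ["PermanovaResult", "permanova_continuous", "compare_time_vs_size"]

EXHAUSTIVE_MAX_N = 7


@dataclass
class PermanovaResult:
    df_model: int
    df_resid: int
    ss_model: float
    ss_resid: float
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int | None
    exhaustive: bool = False

    @property
    def ss_total(self) -> float:
        return self.ss_model + self.ss_resid

    @property
    def mean_sq_model(self) -> float:
        return self.ss_model / self.df_model

    @property
    def mean_sq_resid(self) -> float:
        return self.ss_resid / self.df_resid


def _model_ss(yc: np.ndarray, xc: np.ndarray) -> float:
    """SS explained by regressing centered response columns on centered x."""
    return float(((xc @ yc) ** 2).sum() / (xc @ xc))


def permanova_continuous(
    response: np.ndarray,
    predictor: np.ndarray,
    n_permutations: int = 10_000,
    seed: int | None = None,
    exhaustive: bool | None = None,
) -> PermanovaResult:
    """One-predictor PERMANOVA on a Euclidean multivariate response.

    Parameters
    ----------
    response
        (n_samples, n_coords) real matrix, e.g. ilr coordinates.
    predictor
        Length-n continuous covariate (day of study, SVL, ...).
    n_permutations
        Number of sampled predictor permutations (ignored in exhaustive
        mode).
    seed
        Seed for the permutation stream; fixing it makes the result
        bit-reproducible.
    exhaustive
        Force or forbid exhaustive enumeration; default enumerates all
        n! orderings whenever n <= 7, where the p-value is exact and
        seed-independent.
    """
    y = np.atleast_2d(np.asarray(response, dtype=float))
    x = np.asarray(predictor, dtype=float)
    n = y.shape[0]
    if x.shape != (n,):
        raise InsufficientDataError(
            f"predictor length {x.shape} does not match {n} response rows"
        )
    if n < 4:
        raise InsufficientDataError(f"need >= 4 samples, have {n}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("constant predictor: design is degenerate")

    yc = y - y.mean(axis=0)
    xc = x - x.mean()
    ss_total = float((yc**2).sum())
    ss_model = _model_ss(yc, xc)
    ss_resid = ss_total - ss_model
    df_model, df_resid = 1, n - 2
    if ss_resid > 0:
        f_obs = (ss_model / df_model) / (ss_resid / df_resid)
    else:  # response exactly linear in the predictor
        f_obs = np.inf

    if exhaustive is None:
        exhaustive = n <= EXHAUSTIVE_MAX_N

    # F is a monotone function of ss_model at fixed total SS, so permuted
    # F comparisons reduce to ss_model comparisons.
    if exhaustive:
        perms = np.array(list(_iter_permutations(range(n))))
        ss_perm = ((xc[perms] @ yc) ** 2).sum(axis=1) / (xc @ xc)
        hits = int(np.sum(ss_perm >= ss_model - 1e-12))
        p = hits / len(perms)
        n_perm_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        # chunked to bound memory at large n_permutations
        remaining = n_permutations
        while remaining > 0:
            block = min(remaining, 2000)
            idx = np.argsort(rng.random((block, n)), axis=1)
            ss_perm = ((xc[idx] @ yc) ** 2).sum(axis=1) / (xc @ xc)
            hits += int(np.sum(ss_perm >= ss_model - 1e-12))
            remaining -= block
        p = (hits + 1) / (n_permutations + 1)
        n_perm_used = n_permutations

    return PermanovaResult(
        df_model=df_model,
        df_resid=df_resid,
        ss_model=ss_model,
        ss_resid=ss_resid,
        pseudo_f=float(f_obs),
        r_squared=float(ss_model / ss_total),
        p_value=float(p),
        n_permutations=n_perm_used,
        seed=seed,
        exhaustive=exhaustive,
    )


def permanova_from_distance_matrix(
    dmat: np.ndarray,
    predictor: np.ndarray,
    n_permutations: int = 10_000,
    seed: int | None = None,
    exhaustive: bool | None = None,
) -> PermanovaResult:
    """Gower-centering formulation operating directly on a distance matrix.

    For Euclidean (e.g. Aitchison) distances this is numerically identical
    to :func:`permanova_continuous` on the underlying coordinates; it is
    retained as the dual route for cross-checking and for callers holding
    only a distance matrix.
    """
    d = np.asarray(dmat, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-8):
        raise DegenerateDesignError("distance matrix must be square and symmetric")
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    # eigendecomposition recovers coordinates realizing the distances
    w, v = np.linalg.eigh(g)
    w = np.clip(w, 0, None)
    coords = v * np.sqrt(w)
    return permanova_continuous(
        coords, predictor, n_permutations=n_permutations, seed=seed,
        exhaustive=exhaustive,
    )


@dataclass
class PredictorComparison:
    by_day: PermanovaResult
    by_svl: PermanovaResult
    preferred: str  # "day" | "svl" | "tie"


def compare_time_vs_size(
    table: PeakTable,
    n_permutations: int = 10_000,
    seed: int | None = None,
    tie_tol: float = 1e-9,
) -> PredictorComparison:
    """Run the ontogeny PERMANOVA with day and with SVL as the predictor.

    Samples lacking an SVL measurement are dropped from *both* runs so the
    two models see identical data; the predictor with the higher R^2 is
    preferred.  Affinely equivalent predictors give identical R^2 and are
    reported as a tie.
    """
    table.validate(require_closed=True)
    keep = ~np.isnan(table.svl)
    if keep.sum() < 4:
        raise InsufficientDataError(
            f"{table.snake_id}: only {int(keep.sum())} samples carry SVL"
        )
    y = ilr(table.abundance[keep])
    res_day = permanova_continuous(
        y, table.sample_days[keep].astype(float),
        n_permutations=n_permutations, seed=seed,
    )
    res_svl = permanova_continuous(
        y, table.svl[keep], n_permutations=n_permutations, seed=seed,
    )
    if abs(res_day.r_squared - res_svl.r_squared) <= tie_tol:
        preferred = "tie"
    elif res_svl.r_squared > res_day.r_squared:
        preferred = "svl"
    else:
        preferred = "day"
    return PredictorComparison(by_day=res_day, by_svl=res_svl, preferred=preferred)
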
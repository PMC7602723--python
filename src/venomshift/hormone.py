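"""Serum testosterone preparation and venom-change regressions.

Assay reads arrive as one or two replicates per bleed in ng/mL.
Preparation averages duplicates, substitutes non-detects at the assay's
lower limit of detection (0.001 ng/mL), and stores the natural log, since
hormone concentrations vary multiplicatively.  The association with venom
change is an ordinary least-squares regression of Aitchison distance from
the juvenile baseline on ln-testosterone, with a collinearity guard that
refuses multiple regression when two candidate predictors (e.g. body size
and testosterone) are too strongly correlated to separate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .compositional import BaselineSeries
from .errors import InsufficientDataError, ParameterError, ValidationError

__all__ = [
    "LOD_NG_ML",
    "HormoneSeries",
    "HormoneRegression",
    "prepare_hormone",
    "regress_distance_on_lnT",
    "collinearity_guard",
]

LOD_NG_ML = 0.001


@dataclass
class HormoneSeries:
    days: np.ndarray
    testosterone: np.ndarray  # ng/mL, LOD-substituted
    below_lod: np.ndarray  # bool flags
    ln_testosterone: np.ndarray
    lod: float = LOD_NG_ML


@dataclass
class HormoneRegression:
    slope: float  # distance units per ln(ng/mL)
    intercept: float
    r_squared: float  # proportion
    p_value: float
    n: int

    @property
    def r_squared_percent(self) -> float:
        return 100.0 * self.r_squared


def prepare_hormone(
    days: Sequence[int],
    reads: Sequence[Sequence[float]],
    nondetect: Sequence[bool] | None = None,
    lod: float = LOD_NG_ML,
) -> HormoneSeries:
    """Average duplicate reads, substitute non-detects at the LOD, take ln.

    ``reads[i]`` holds one or two replicate concentrations for sample i;
    a value below the LOD, or an explicit non-detect flag, is set to the
    LOD itself.  Substitution is idempotent: the LOD value maps to itself.
    """
    days = np.asarray(days, dtype=float)
    if nondetect is None:
        nondetect = [False] * len(days)
    if not (len(days) == len(reads) == len(nondetect)):
        raise ValidationError("days, reads and nondetect flags must align")
    values, flags = [], []
    for i, sample_reads in enumerate(reads):
        arr = np.asarray(sample_reads, dtype=float).ravel()
        if arr.size not in (1, 2):
            raise ValidationError(f"sample {i}: expected 1 or 2 reads, got {arr.size}")
        if np.any(arr < 0):
            raise ValidationError(f"sample {i}: negative concentration read")
        mean = float(arr.mean())
        below = bool(nondetect[i]) or mean < lod
        values.append(lod if below else mean)
        flags.append(below)
    values = np.asarray(values)
    return HormoneSeries(
        days=days,
        testosterone=values,
        below_lod=np.asarray(flags, dtype=bool),
        ln_testosterone=np.log(values),
        lod=lod,
    )


def regress_distance_on_lnT(
    distances: BaselineSeries,
    hormone: HormoneSeries,
    match_window_days: int = 0,
    use_scaled: bool = False,
) -> HormoneRegression:
    """OLS of venom distance from baseline on ln-testosterone.

    Venom and blood series are matched by collection day, exactly by
    default or within ``match_window_days`` for jittered schedules.  Raw
    distances are regressed unless ``use_scaled`` is set.
    """
    d_vals = (
        distances.scaled_distances if use_scaled else distances.distances
    )
    if d_vals is None:
        raise ParameterError("requested scaled distances but series is unscaled")
    pairs_d, pairs_t = [], []
    for day, dist in zip(distances.days, d_vals):
        gaps = np.abs(hormone.days - day)
        j = int(np.argmin(gaps))
        if gaps[j] <= match_window_days:
            pairs_d.append(dist)
            pairs_t.append(hormone.ln_testosterone[j])
    if len(pairs_d) < 4:
        raise InsufficientDataError(
            f"only {len(pairs_d)} venom/blood sample pairs matched; need >= 4"
        )
    res = stats.linregress(pairs_t, pairs_d)
    return HormoneRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(pairs_d),
    )


def collinearity_guard(
    predictor_a: Sequence[float],
    predictor_b: Sequence[float],
    threshold: float = 0.7,
) -> tuple[bool, float]:
    """Pearson-correlation gate for multiple regression.

    Returns ``(allow, r)``: ``allow`` is False when |r| exceeds the
    threshold, in which case a joint model of the two predictors cannot
    attribute variance between them and should not be fit.
    """
    a = np.asarray(predictor_a, dtype=float)
    b = np.asarray(predictor_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("predictors must be matching 1-D vectors")
    if len(a) < 4:
        raise InsufficientDataError("need >= 4 paired observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ParameterError("correlation undefined for a constant predictor")
    r = float(stats.pearsonr(a, b).statistic)
    return (abs(r) <= threshold, r)
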
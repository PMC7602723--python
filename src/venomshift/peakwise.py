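"""Per-peak clr-abundance trajectory scan.

A gradual whole-venom shift can hide a mixture of behaviors among
individual toxin peaks: the scan models the clr-transformed abundance of
every peak against time, classifies each as no-shift / linear-gradual /
sigmoid-gradual / sigmoid-discrete with the same rule used for the
whole-venom trajectory, and tabulates the counts.

Because the data are compositional, a genuine rise in one peak forces
relative drops elsewhere; detected shifts in non-manipulated peaks of a
simulation are therefore expected, and detection claims should be read as
"this peak's relative abundance shifted", not "this gene's expression
changed".  No multiple-testing correction is applied by default;
Benjamini-Hochberg is available via ``mtc="bh"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compositional import PeakTable, clr
from .errors import InsufficientDataError, ParameterError
from .trajectory import SEASON_DAYS, classify_series

__all__ = ["PeakShiftSummary", "PeakShiftReport", "peak_shift_scan", "summarize_counts"]

MODES = ("no_shift", "linear_gradual", "sigmoid_gradual", "sigmoid_discrete")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class PeakShiftSummary:
    n_no_shift: int
    n_linear_gradual: int
    n_sigmoid_gradual: int
    n_sigmoid_discrete: int
    proportion_shifting: str  # "a/b, c%"
    percent_gradual: int | None  # None when no peak shifts

    @property
    def n_total(self) -> int:
        return (
            self.n_no_shift
            + self.n_linear_gradual
            + self.n_sigmoid_gradual
            + self.n_sigmoid_discrete
        )

    @property
    def n_shifting(self) -> int:
        return self.n_linear_gradual + self.n_sigmoid_gradual + self.n_sigmoid_discrete


@dataclass
class PeakShiftReport:
    snake_id: str
    per_peak: pd.DataFrame  # peak_id, mode, tempo_days, p_value, delta_aicc
    summary: PeakShiftSummary


def summarize_counts(
    n_no_shift: int,
    n_linear_gradual: int,
    n_sigmoid_gradual: int,
    n_sigmoid_discrete: int,
) -> PeakShiftSummary:
    """Tabulate mode counts into the shifting proportion and percent gradual.

    ``proportion_shifting`` is "shifting/total, percent%"; ``percent_gradual``
    is the linear-gradual plus sigmoid-gradual count over the number of
    significantly shifting peaks, rounded half away from zero.  With no
    shifting peaks the percent is undefined and reported as missing.
    """
    counts = (n_no_shift, n_linear_gradual, n_sigmoid_gradual, n_sigmoid_discrete)
    if any(c < 0 for c in counts):
        raise ParameterError("mode counts must be nonnegative")
    total = sum(counts)
    if total == 0:
        raise ParameterError("empty report: all mode counts are zero")
    shifting = n_linear_gradual + n_sigmoid_gradual + n_sigmoid_discrete
    pct_shifting = _round_half_up(100 * shifting / total)
    if shifting > 0:
        percent_gradual = _round_half_up(
            100 * (n_linear_gradual + n_sigmoid_gradual) / shifting
        )
    else:
        percent_gradual = None
    return PeakShiftSummary(
        n_no_shift=n_no_shift,
        n_linear_gradual=n_linear_gradual,
        n_sigmoid_gradual=n_sigmoid_gradual,
        n_sigmoid_discrete=n_sigmoid_discrete,
        proportion_shifting=f"{shifting}/{total}, {pct_shifting}%",
        percent_gradual=percent_gradual,
    )


def peak_shift_scan(
    table: PeakTable,
    alpha: float = 0.05,
    season_days: float = SEASON_DAYS,
    seed: int | None = None,
    mtc: str | None = None,
    tempo_formula: str = "max_rate",
    decisive_delta: float = 2.0,
    n_baseline: int = 3,
) -> PeakShiftReport:
    """Classify the ontogenetic mode of every peak in an individual's table.

    The full abundance matrix is clr-transformed once (zeros must have
    been replaced); each peak's clr coordinate, centered on its own
    juvenile reference (the mean over the ``n_baseline`` earliest
    samples, mirroring the whole-venom baseline), is regressed on day of
    study through the linear/sigmoid competition.  The centering puts the
    series' left asymptote near zero so the 3-parameter logistic applies,
    with a signed amplitude since a peak's relative abundance may fall as
    well as rise.  Tempo for linear-mode peaks is the sampling span,
    mirroring the whole-venom rule.
    """
    table.validate(require_closed=True)
    if table.n_samples < 5:
        raise InsufficientDataError(
            f"{table.snake_id}: peak scan needs >= 5 samples, have {table.n_samples}"
        )
    if np.any(table.abundance <= 0):
        raise ParameterError("zeros present: apply replace_zeros before the scan")
    if mtc not in (None, "bh"):
        raise ParameterError(f"unknown multiple-testing correction {mtc!r}")

    z = clr(table.abundance)
    z = z - z[:n_baseline].mean(axis=0)  # juvenile-reference centering
    t = table.sample_days.astype(float)

    rows = []
    for j, peak_id in enumerate(table.peak_ids):
        linear, sig, cls = classify_series(
            t,
            z[:, j],
            sign_free=True,
            alpha=alpha,
            season_days=season_days,
            decisive_delta=decisive_delta,
            tempo_formula=tempo_formula,
            seed=seed,
        )
        rows.append(
            {
                "peak_id": peak_id,
                "retention_time": float(table.retention_times[j]),
                "mode": cls.mode,
                "tempo_days": cls.tempo_days,
                "p_value": cls.p_value,
                "delta_aicc": cls.delta_aicc,
                "best_model": cls.best_model,
            }
        )
    per_peak = pd.DataFrame(rows)

    if mtc == "bh":
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, _, _ = multipletests(
            per_peak["p_value"].to_numpy(), alpha=alpha, method="fdr_bh"
        )
        per_peak["p_adjusted"] = p_adj
        # a peak surviving correction keeps its fitted mode; one failing it
        # is demoted to no_shift
        per_peak.loc[~reject, "mode"] = "no_shift"

    mode_counts = {m: int((per_peak["mode"] == m).sum()) for m in MODES}
    summary = summarize_counts(
        mode_counts["no_shift"],
        mode_counts["linear_gradual"],
        mode_counts["sigmoid_gradual"],
        mode_counts["sigmoid_discrete"],
    )
    return PeakShiftReport(snake_id=table.snake_id, per_peak=per_peak, summary=summary)
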
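"""Readers, writers, the minor-peak filter, and the full per-snake report.

Peak-table files are delimited text, one row per sample, with columns
``sample_id``, ``date`` (ISO 8601), ``svl_cm`` (may be empty) and one
column per peak named ``peak_<k>@<retention_min>``.  Dates are converted
to integer days since the individual's first sample; day counts are plain
calendar-day differences.

``run_full_report`` chains the stages — minor-peak filter, zero
replacement, whole-venom PERMANOVA, baseline-distance trajectory with the
linear/sigmoid competition, the per-peak scan, and optionally the hormone
regression and the shared NMDS venom space — into one bundle of tidy
DataFrames, logging every threshold used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import peakwise, permanova, trajectory
from .compositional import (
    BaselineSeries,
    PeakTable,
    baseline_distance_series,
    close,
    replace_zeros,
)
from .errors import ParameterError, ValidationError
from .hormone import HormoneRegression, HormoneSeries, prepare_hormone, regress_distance_on_lnT
from .venom_space import NmdsResult, bin_retention_windows, nmds, pairwise_aitchison

logger = logging.getLogger("venomshift")

__all__ = [
    "RunConfig",
    "SnakeReport",
    "ReportBundle",
    "read_peak_table",
    "write_peak_table",
    "read_hormone_table",
    "write_baseline_series",
    "filter_minor_peaks",
    "run_full_report",
]


@dataclass
class RunConfig:
    """Thresholds and seeds shared by the full pipeline."""

    n_baseline: int = 3
    min_peak_fraction: float = 0.001  # 0.1% mean-abundance noise floor
    zero_delta: float = 6.5e-4
    n_permutations: int = 10_000
    alpha: float = 0.05
    season_days: float = trajectory.SEASON_DAYS
    tempo_formula: str = "max_rate"
    decisive_delta: float = 2.0
    seed: int = 0
    nmds_starts: int = 20

    def __post_init__(self) -> None:
        for name in ("min_peak_fraction", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ParameterError(f"{name} must lie in (0, 1), got {v}")
        if self.season_days <= 0:
            raise ParameterError("season_days must be positive")


def read_peak_table(
    path: str | Path,
    snake_id: str | None = None,
    species: str = "",
    sep: str = ",",
) -> PeakTable:
    """Load one individual's longitudinal peak table from delimited text."""
    df = pd.read_csv(path, sep=sep)
    required = {"sample_id", "date"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")
    peak_cols = [c for c in df.columns if c.startswith("peak_") and "@" in c]
    if not peak_cols:
        raise ValidationError(f"{path}: no 'peak_<k>@<retention_min>' columns found")
    dates = pd.to_datetime(df["date"], format="ISO8601")
    order = np.argsort(dates.to_numpy(), kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    dates = dates.iloc[order].reset_index(drop=True)
    days = (dates - dates.iloc[0]).dt.days.to_numpy()
    svl = (
        pd.to_numeric(df["svl_cm"], errors="coerce").to_numpy()
        if "svl_cm" in df.columns
        else np.full(len(df), np.nan)
    )
    rts = np.array([float(c.split("@", 1)[1]) for c in peak_cols])
    return PeakTable(
        snake_id=snake_id or str(Path(path).stem),
        species=species,
        sample_days=days,
        svl=svl,
        peak_ids=peak_cols,
        retention_times=rts,
        abundance=df[peak_cols].to_numpy(dtype=float),
        sample_ids=df["sample_id"].astype(str).tolist(),
    )


def write_peak_table(
    table: PeakTable,
    path: str | Path,
    start_date: str = "2013-01-01",
    sep: str = ",",
) -> None:
    """Write a peak table in the same layout ``read_peak_table`` consumes."""
    dates = pd.Timestamp(start_date) + pd.to_timedelta(table.sample_days, unit="D")
    cols = {}
    for pid, rt in zip(table.peak_ids, table.retention_times):
        name = pid if "@" in pid else f"{pid}@{rt:.12g}"
        cols[name] = None
    df = pd.DataFrame(table.abundance, columns=list(cols))
    df.insert(0, "sample_id", table.sample_ids)
    df.insert(1, "date", dates.strftime("%Y-%m-%d"))
    df.insert(2, "svl_cm", table.svl)
    df.to_csv(path, sep=sep, index=False)


def read_hormone_table(path: str | Path, sep: str = ",") -> HormoneSeries:
    """Load assay reads: sample_id, date, read1_ng_ml[, read2_ng_ml, nondetect]."""
    df = pd.read_csv(path, sep=sep)
    for col in ("date", "read1_ng_ml"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    dates = pd.to_datetime(df["date"], format="ISO8601")
    order = np.argsort(dates.to_numpy(), kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    dates = dates.iloc[order].reset_index(drop=True)
    days = (dates - dates.iloc[0]).dt.days.to_numpy()
    reads = []
    for _, row in df.iterrows():
        r = [row["read1_ng_ml"]]
        if "read2_ng_ml" in df.columns and pd.notna(row.get("read2_ng_ml")):
            r.append(row["read2_ng_ml"])
        reads.append(r)
    nondetect = (
        df["nondetect"].astype(bool).tolist() if "nondetect" in df.columns else None
    )
    return prepare_hormone(days, reads, nondetect)


def write_baseline_series(series: BaselineSeries, path: str | Path, sep: str = ",") -> None:
    series.to_frame().to_csv(path, sep=sep, index=False)


def filter_minor_peaks(table: PeakTable, min_fraction: float = 0.001) -> PeakTable:
    """Drop peaks whose mean relative abundance is below the noise floor.

    The filter acts per peak on the mean across samples (a peak is an
    entity of the individual, not of a single chromatogram); remaining
    rows are re-closed, which preserves ratios among retained peaks.
    """
    table.validate(require_closed=True)
    if not 0 < min_fraction < 1:
        raise ParameterError("min_fraction must lie in (0, 1)")
    mean_ab = table.abundance.mean(axis=0)
    keep = mean_ab >= min_fraction
    if not keep.any():
        raise ValidationError(
            f"{table.snake_id}: the {min_fraction:.3%} filter would drop every peak"
        )
    dropped = [p for p, k in zip(table.peak_ids, keep) if not k]
    if dropped:
        logger.info("%s: dropped %d minor peak(s): %s", table.snake_id, len(dropped), dropped)
    if keep.sum() == 1:
        logger.warning("%s: a single peak remains; composition is degenerate", table.snake_id)
    out = PeakTable(
        snake_id=table.snake_id,
        species=table.species,
        sample_days=table.sample_days.copy(),
        svl=table.svl.copy(),
        peak_ids=[p for p, k in zip(table.peak_ids, keep) if k],
        retention_times=table.retention_times[keep],
        abundance=close(table.abundance[:, keep]),
        sample_ids=list(table.sample_ids),
    )
    return out


@dataclass
class SnakeReport:
    snake_id: str
    permanova: permanova.PermanovaResult
    baseline: BaselineSeries
    linear_fit: trajectory.TrajectoryFit
    sigmoid_fit: trajectory.TrajectoryFit | None
    classification: trajectory.ShiftClassification
    peak_report: peakwise.PeakShiftReport
    hormone_regression: HormoneRegression | None = None


@dataclass
class ReportBundle:
    snakes: dict[str, SnakeReport]
    permanova_table: pd.DataFrame  # Df, SumsOfSqs, MeanSqs, F, R2, p per snake
    trajectory_table: pd.DataFrame  # AICc/R2/p for both models + tempo + mode
    peak_summary_table: pd.DataFrame  # mode counts + shifting/gradual summary
    venom_space: NmdsResult | None = None
    venom_space_samples: pd.DataFrame | None = None


def _analyze_snake(
    table: PeakTable,
    config: RunConfig,
    hormone: HormoneSeries | None,
) -> SnakeReport:
    from .compositional import ilr

    filtered = filter_minor_peaks(table, config.min_peak_fraction)
    ab = filtered.abundance
    if np.any(ab == 0):
        ab = replace_zeros(ab, delta=config.zero_delta)
    clean = filtered.with_abundance(ab)

    perm = permanova.permanova_continuous(
        ilr(clean.abundance),
        clean.sample_days.astype(float),
        n_permutations=config.n_permutations,
        seed=config.seed,
    )
    baseline = baseline_distance_series(clean, n_baseline=config.n_baseline, scale=True)
    linear, sig, cls = trajectory.classify_series(
        clean.sample_days.astype(float),
        baseline.scaled_distances,
        alpha=config.alpha,
        season_days=config.season_days,
        decisive_delta=config.decisive_delta,
        tempo_formula=config.tempo_formula,
        seed=config.seed,
    )
    peaks = peakwise.peak_shift_scan(
        clean,
        alpha=config.alpha,
        season_days=config.season_days,
        seed=config.seed,
        tempo_formula=config.tempo_formula,
        decisive_delta=config.decisive_delta,
    )
    horm_reg = None
    if hormone is not None:
        try:
            horm_reg = regress_distance_on_lnT(baseline, hormone)
        except Exception as exc:  # graceful degradation: venom stages stand
            logger.warning("%s: hormone regression skipped (%s)", table.snake_id, exc)
    return SnakeReport(
        snake_id=table.snake_id,
        permanova=perm,
        baseline=baseline,
        linear_fit=linear,
        sigmoid_fit=sig,
        classification=cls,
        peak_report=peaks,
        hormone_regression=horm_reg,
    )


def run_full_report(
    tables: list[PeakTable],
    config: RunConfig | None = None,
    hormones: dict[str, HormoneSeries] | None = None,
    include_venom_space: bool = True,
) -> ReportBundle:
    """Run every analysis stage on a set of individuals.

    ``hormones`` maps snake_id to a prepared series; individuals without
    one simply skip the hormone stage.  The shared venom space needs at
    least four samples overall and more than one individual to be
    informative, but is computed whenever enough samples exist.
    """
    config = config or RunConfig()
    hormones = hormones or {}
    logger.info(
        "pipeline config: n_baseline=%d min_peak_fraction=%g n_permutations=%d "
        "alpha=%g season_days=%g tempo=%s seed=%d",
        config.n_baseline, config.min_peak_fraction, config.n_permutations,
        config.alpha, config.season_days, config.tempo_formula, config.seed,
    )
    snakes: dict[str, SnakeReport] = {}
    for table in tables:
        try:
            snakes[table.snake_id] = _analyze_snake(
                table, config, hormones.get(table.snake_id)
            )
        except Exception as exc:
            raise type(exc)(f"[snake {table.snake_id}] {exc}") from exc

    perm_rows, traj_rows, peak_rows = [], [], []
    for sid, rep in snakes.items():
        p = rep.permanova
        perm_rows.append(
            {
                "snake_id": sid, "Df": p.df_model, "SumsOfSqs": p.ss_model,
                "MeanSqs": p.mean_sq_model, "F": p.pseudo_f, "R2": p.r_squared,
                "p": p.p_value,
            }
        )
        lin, sig, cls = rep.linear_fit, rep.sigmoid_fit, rep.classification
        traj_rows.append(
            {
                "snake_id": sid,
                "aicc_linear": lin.aicc, "r2_linear": lin.r_squared, "p_linear": lin.p_value,
                "aicc_sigmoid": sig.aicc if sig else np.nan,
                "r2_sigmoid": sig.r_squared if sig else np.nan,
                "p_sigmoid": sig.p_value if sig else np.nan,
                "tempo_days": cls.tempo_days, "mode": cls.mode,
            }
        )
        s = rep.peak_report.summary
        peak_rows.append(
            {
                "snake_id": sid, "no_shift": s.n_no_shift,
                "linear_gradual": s.n_linear_gradual,
                "sigmoid_gradual": s.n_sigmoid_gradual,
                "sigmoid_discrete": s.n_sigmoid_discrete,
                "proportion_shifting": s.proportion_shifting,
                "percent_gradual": s.percent_gradual,
            }
        )

    space = None
    space_samples = None
    if include_venom_space:
        binned = bin_retention_windows(tables)
        if binned.binned_abundance.shape[0] >= 4:
            dmat = pairwise_aitchison(binned.binned_abundance, delta=config.zero_delta)
            space = nmds(dmat, n_starts=config.nmds_starts, seed=config.seed)
            space_samples = pd.DataFrame(
                {
                    "snake_id": binned.snake_ids,
                    "sample_id": binned.sample_ids,
                    "day": binned.sample_days,
                    "axis1": space.coords[:, 0],
                    "axis2": space.coords[:, 1],
                }
            )
        else:
            logger.warning("venom space skipped: fewer than 4 samples overall")

    return ReportBundle(
        snakes=snakes,
        permanova_table=pd.DataFrame(perm_rows),
        trajectory_table=pd.DataFrame(traj_rows),
        peak_summary_table=pd.DataFrame(peak_rows),
        venom_space=space,
        venom_space_samples=space_samples,
    )
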
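"""Size-structured diet analysis.

Published gut-content records pair a snake's snout-vent length (SVL, mm)
with a prey category.  Snakes are binned into four equal-width size
classes spanning the shortest to the longest snake in the dataset, prey
are tallied per class, and adjacent size classes are contrasted with
Pearson chi-square tests — the test of whether diet composition shifts
as snakes grow.

Bin edges use an integer-width convention: with records spanning
512-1595 mm the classes are 512-782, 783-1053, 1054-1324, 1325-1595 mm
(width (max - min + 1)/4 = 271).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .errors import ParameterError, ValidationError

__all__ = [
    "PREY_ORDER",
    "DietTable",
    "AdjacentChiSquare",
    "bin_svl_quartiles",
    "chisq_adjacent",
]

# fixed smallest-to-largest average prey size orderings per species
PREY_ORDER = {
    "C. horridus": ["shrews", "mice", "voles", "chipmunks", "rats", "squirrels", "rabbits"],
    "C. adamanteus": ["mice", "rats", "squirrels", "rabbits"],
}


@dataclass
class DietTable:
    species: str
    svl_bounds_mm: list[tuple[float, float]]  # 4 (lo, hi) inclusive bounds
    prey_categories: list[str]
    counts: np.ndarray  # 4 x C integers
    totals: np.ndarray  # per-bin totals

    def proportions(self) -> pd.DataFrame:
        with np.errstate(invalid="ignore"):
            props = self.counts / self.totals[:, None]
        labels = [f"{int(lo)}-{int(hi)}" for lo, hi in self.svl_bounds_mm]
        return pd.DataFrame(props, index=labels, columns=self.prey_categories)


@dataclass
class AdjacentChiSquare:
    pair: tuple[int, int]  # 0-based quartile indices
    statistic: float
    p_value: float
    df: int
    low_expected: bool  # any expected cell < 5
    skipped: bool = False


def bin_svl_quartiles(
    svl_mm: Sequence[float],
    prey_category: Sequence[str],
    species: str = "",
    category_order: Sequence[str] | None = None,
) -> DietTable:
    """Tally prey categories within four equal-width SVL classes.

    The class width is ``(max - min + 1)/4`` of the observed SVL range
    (record SVLs are reported to the mm); the last class is closed at the
    maximum so every record falls in exactly one class and totals are
    conserved.
    """
    svl = np.asarray(svl_mm, dtype=float)
    prey = list(prey_category)
    if len(svl) != len(prey):
        raise ValidationError("svl and prey vectors must align")
    if np.any(svl <= 0):
        raise ValidationError("SVL must be positive")
    lo, hi = float(svl.min()), float(svl.max())
    if lo == hi:
        raise ParameterError("degenerate SVL range: need >= 2 distinct lengths")

    if category_order is None:
        category_order = PREY_ORDER.get(species) or sorted(set(prey))
    unknown = set(prey) - set(category_order)
    if unknown:
        raise ValidationError(f"prey categories not in the ordering: {sorted(unknown)}")

    width = (hi - lo + 1) / 4
    idx = np.minimum(((svl - lo) // width).astype(int), 3)
    bounds = [(lo + k * width, lo + (k + 1) * width - 1) for k in range(4)]
    bounds[3] = (bounds[3][0], hi)

    cat_pos = {c: j for j, c in enumerate(category_order)}
    counts = np.zeros((4, len(category_order)), dtype=int)
    for i, p in zip(idx, prey):
        counts[i, cat_pos[p]] += 1
    return DietTable(
        species=species,
        svl_bounds_mm=bounds,
        prey_categories=list(category_order),
        counts=counts,
        totals=counts.sum(axis=1),
    )


def chisq_adjacent(table: DietTable) -> list[AdjacentChiSquare]:
    """Pearson chi-square contrasts between adjacent size classes.

    Each 2 x C count table drops prey categories absent from both classes
    (df = remaining categories - 1); no continuity correction.  A class
    with zero records is skipped with a flag rather than tested.
    """
    results = []
    for q in range(3):
        pair = (q, q + 1)
        sub = table.counts[[q, q + 1], :]
        if sub.sum(axis=1).min() == 0:
            results.append(
                AdjacentChiSquare(pair, float("nan"), float("nan"), 0, False, skipped=True)
            )
            continue
        sub = sub[:, sub.sum(axis=0) > 0]
        if sub.shape[1] < 2:
            # a single shared category carries no compositional contrast
            results.append(AdjacentChiSquare(pair, 0.0, 1.0, 0, False))
            continue
        stat, p, df, expected = chi2_contingency(sub, correction=False)
        results.append(
            AdjacentChiSquare(
                pair=pair,
                statistic=float(stat),
                p_value=float(p),
                df=int(df),
                low_expected=bool((expected < 5).any()),
            )
        )
    return results
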
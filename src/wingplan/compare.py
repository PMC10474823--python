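"""Method-comparison statistics for paired spread-wing / folded-wing estimates.

Interspecific agreement is summarised by a log-scale discrepancy (the sum of
paired log10 differences, folded minus spread, so a model that underestimates
area has negative discrepancy); intraspecific accuracy and precision by the
mean percent difference between methods and by coefficients of variation.
Because the same specimens underlie both methods, a lower CV for one method
reflects lower measurement error of that method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PairedEstimates",
    "ComparisonSummary",
    "log10_discrepancy",
    "percent_difference",
    "coefficient_of_variation",
    "intraspecific_summary",
    "summarize_by_species",
    "bland_altman_frame",
    "plot_bland_altman",
    "round_half_away",
]


@dataclass(frozen=True)
class PairedEstimates:
    """Per-specimen paired values from two methods of the same quantity.

    ``table`` must carry columns ``id``, ``species``, ``value_spread``,
    ``value_folded``; ``quantity`` names what the values are
    (``"area"`` or ``"aspect_ratio"``).
    """

    table: pd.DataFrame
    quantity: str = "area"

    REQUIRED = ("id", "species", "value_spread", "value_folded")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"paired table is missing columns {missing}")
        vals = self.table[["value_spread", "value_folded"]].to_numpy(float)
        if not np.isfinite(vals).all() or (vals <= 0).any():
            raise ValueError("paired values must be positive and finite")

    @property
    def folded(self) -> np.ndarray:
        return self.table["value_folded"].to_numpy(float)

    @property
    def spread(self) -> np.ndarray:
        return self.table["value_spread"].to_numpy(float)

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class ComparisonSummary:
    """One species x model row of the intraspecific comparison."""

    species: str
    n: int
    mean_spread: float
    mean_folded: float
    sd_spread: float
    sd_folded: float
    cv_spread: float
    cv_folded: float
    mean_pct_diff: float
    discrepancy: float
    diff_mode: str = "ratio-of-means"

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def log10_discrepancy(pairs: PairedEstimates) -> float:
    """Sum over specimens of log10(folded) - log10(spread).

    Log transformation removes body-size scaling (and the attendant
    heteroscedasticity), making contributions comparable between a
    hummingbird and a swan.  The statistic is additive over disjoint
    specimen subsets; for aspect ratios computed with a shared wingspan it
    is the exact negative of the area discrepancy.
    """
    return float(np.sum(np.log10(pairs.folded) - np.log10(pairs.spread)))


def percent_difference(folded_mean: float, spread_mean: float) -> float:
    """Difference of the folded-wing mean from the spread-wing mean, in %.

    ``100 * (folded - spread) / spread``: the spread-wing method is the
    reference denominator.  Not symmetric in its arguments.
    """
    if spread_mean <= 0:
        raise ValueError(f"spread-wing mean must be positive, got {spread_mean!r}")
    return 100.0 * (folded_mean - spread_mean) / spread_mean


def coefficient_of_variation(values) -> float:
    """Sample coefficient of variation in percent: 100 * SD / mean.

    Uses the n-1 (sample) standard deviation; requires at least two values
    and a positive mean.  Invariant under rescaling of the values.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError(f"need at least 2 values for a CV, got {arr.size}")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError(f"CV requires a positive mean, got {mean}")
    return float(100.0 * arr.std(ddof=1) / mean)


def intraspecific_summary(
    pairs: PairedEstimates,
    *,
    diff_mode: str = "ratio-of-means",
) -> ComparisonSummary:
    """Accuracy/precision summary for one species' paired estimates.

    Emits per-method mean, SD and CV plus the mean percent difference of
    the folded-wing method from the spread-wing method.  ``diff_mode``
    selects how that difference is aggregated:

    ``"ratio-of-means"``
        percent difference of the mean folded value from the mean spread
        value (the default);
    ``"mean-of-ratios"``
        mean of the per-specimen percent differences.

    The two agree to first order but can differ at display rounding.
    """
    species = pairs.table["species"].unique()
    if len(species) != 1:
        raise ValueError(
            f"intraspecific summary needs a single species, got {sorted(species)}"
        )
    if len(pairs) < 2:
        raise ValueError("need >= 2 specimens for an intraspecific summary")
    folded, spread = pairs.folded, pairs.spread
    if diff_mode == "ratio-of-means":
        pct = percent_difference(folded.mean(), spread.mean())
    elif diff_mode == "mean-of-ratios":
        pct = float(np.mean([percent_difference(f, s) for f, s in zip(folded, spread)]))
    else:
        raise ValueError(
            f"diff_mode must be 'ratio-of-means' or 'mean-of-ratios', got {diff_mode!r}"
        )
    return ComparisonSummary(
        species=str(species[0]),
        n=len(pairs),
        mean_spread=float(spread.mean()),
        mean_folded=float(folded.mean()),
        sd_spread=float(spread.std(ddof=1)),
        sd_folded=float(folded.std(ddof=1)),
        cv_spread=coefficient_of_variation(spread),
        cv_folded=coefficient_of_variation(folded),
        mean_pct_diff=pct,
        discrepancy=log10_discrepancy(pairs),
        diff_mode=diff_mode,
    )


def summarize_by_species(
    pairs: PairedEstimates, *, diff_mode: str = "ratio-of-means"
) -> pd.DataFrame:
    """Tidy frame of :func:`intraspecific_summary` rows, one per species."""
    rows = []
    for species, sub in pairs.table.groupby("species", sort=True):
        if len(sub) < 2:
            continue
        summary = intraspecific_summary(
            PairedEstimates(sub.reset_index(drop=True), pairs.quantity),
            diff_mode=diff_mode,
        )
        rows.append(summary.to_dict())
    return pd.DataFrame(rows)


def bland_altman_frame(pairs: PairedEstimates) -> pd.DataFrame:
    """Per-specimen log10 difference vs log10 mean (Bland-Altman coordinates)."""
    lf, ls = np.log10(pairs.folded), np.log10(pairs.spread)
    return pd.DataFrame(
        {
            "id": pairs.table["id"].to_numpy(),
            "species": pairs.table["species"].to_numpy(),
            "log10_mean": (lf + ls) / 2.0,
            "log10_diff": lf - ls,
        }
    )


def plot_bland_altman(pairs: PairedEstimates, ax=None):
    """Bland-Altman agreement plot on the log10 scale.

    Scatters each specimen's log10(folded) - log10(spread) against the
    log10 mean of the two values, with the zero line and the mean
    difference marked.  Returns the matplotlib axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ba = bland_altman_frame(pairs)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba["log10_mean"], ba["log10_diff"], s=18, alpha=0.7)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.axhline(float(ba["log10_diff"].mean()), color="C1", ls="--", lw=0.8,
               label="mean difference")
    ax.set_xlabel(f"log10 mean {pairs.quantity}")
    ax.set_ylabel("log10 (folded) − log10 (spread)")
    ax.legend(frameon=False)
    return ax


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round with halves away from zero (display parity with printed tables)."""
    q = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)
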
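"""Quantification of liquid-culture senescence assays.

Cultures are grown for 24 h, counted, and diluted back to a fixed density
(2 x 10^5 cells/ml by default) every day.  Each passage therefore measures
one population-doubling (PD) increment, log2(density / dilution_density),
and senescence is tracked on a cumulative-PD axis rather than in days
because telomere shortening is a function of cell division, not time.  The
point of maximum senescence is the passage of minimum density (the trough
before survivor outgrowth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_DILUTION_DENSITY = 2e5


@dataclass
class SenescenceCurve:
    """One replicate of a serial-dilution senescence assay."""

    strain_id: str
    genotype: str
    replicate_id: str
    days: np.ndarray
    densities: np.ndarray
    pd_increments: np.ndarray
    cumulative_pd: np.ndarray
    trough_day: int
    max_senescence_pd: float
    dilution_density: float = DEFAULT_DILUTION_DENSITY
    shrinking_days: list[int] = field(default_factory=list)

    @property
    def first_day_after_trough(self) -> int:
        """First time point after the point of maximum senescence (the
        passage at which survivors are typically sampled)."""
        return self.trough_day + 1


@dataclass
class GenotypeSummary:
    """Per-passage mean +/- SE across the replicates of one genotype."""

    genotype: str
    n_replicates: int
    table: pd.DataFrame  # day, mean_cumulative_pd, se_cumulative_pd, mean_density, se_density


def population_doublings(density: float, dilution_density: float = DEFAULT_DILUTION_DENSITY) -> float:
    """PD increment of one passage: log2(density / dilution_density).

    Negative for cultures that shrank below the dilution density; the value
    is recorded as-is so cumulative PD honestly reflects population decline.
    """
    if density <= 0 or dilution_density <= 0:
        raise ValueError("densities must be positive")
    return float(np.log2(density / dilution_density))


def build_curve(
    rows: pd.DataFrame,
    dilution_density: float = DEFAULT_DILUTION_DENSITY,
) -> SenescenceCurve:
    """Convert one replicate's daily densities into a senescence curve.

    ``rows`` must carry columns day/density (plus strain_id, genotype,
    replicate_id) with consecutive days from 1.  The point of maximum
    senescence is the day of minimum density; ties resolve to the earliest
    day.
    """
    rows = rows.sort_values("day")
    days = rows["day"].to_numpy(dtype=int)
    if list(days) != list(range(1, len(days) + 1)):
        raise ValueError(f"days are not consecutive from 1: {list(days)}")
    dens = rows["density"].to_numpy(dtype=float)
    if (dens <= 0).any():
        raise ValueError("non-positive density")
    incr = np.log2(dens / dilution_density)
    cum = np.cumsum(incr)
    trough_idx = int(np.argmin(dens))  # argmin takes the earliest tie
    meta = rows.iloc[0]
    return SenescenceCurve(
        strain_id=str(meta.get("strain_id", "")),
        genotype=str(meta.get("genotype", "")),
        replicate_id=str(meta.get("replicate_id", "")),
        days=days,
        densities=dens,
        pd_increments=incr,
        cumulative_pd=cum,
        trough_day=int(days[trough_idx]),
        max_senescence_pd=float(cum[trough_idx]),
        dilution_density=dilution_density,
        shrinking_days=[int(d) for d, x in zip(days, incr) if x < 0],
    )


def build_curves(
    table: pd.DataFrame, dilution_density: float = DEFAULT_DILUTION_DENSITY
) -> list[SenescenceCurve]:
    """Build one curve per (strain_id, replicate_id) of a density table."""
    out = []
    for _, grp in table.groupby(["strain_id", "replicate_id"], sort=True):
        out.append(build_curve(grp, dilution_density))
    return out


def compare_genotypes(
    curves_a: Sequence[SenescenceCurve], curves_b: Sequence[SenescenceCurve]
) -> float:
    """Unpaired two-tailed Welch t-test on PDs at maximum senescence.

    Welch's unequal-variance form is used because replicate counts
    typically differ between genotypes (e.g. 5 vs 10 spore isolates).
    """
    if len(curves_a) < 2 or len(curves_b) < 2:
        raise ValueError("compare_genotypes requires >= 2 replicates per genotype")
    a = np.asarray([c.max_senescence_pd for c in curves_a], dtype=float)
    b = np.asarray([c.max_senescence_pd for c in curves_b], dtype=float)
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return 1.0  # degenerate identical groups
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


def summarize_genotype(curves: Sequence[SenescenceCurve]) -> GenotypeSummary:
    """Per-passage mean and SE of cumulative PD and of density.

    Replicates are aligned by passage number (day index): each daily passage
    is one measurement event, and the mean cumulative PD then serves as the
    plotting x-axis.  SE is the sample SD / sqrt(n), reported only for
    passages with >= 2 replicates.
    """
    if len(curves) == 0:
        raise ValueError("summarize_genotype requires at least one curve")
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "day": c.days,
                    "cumulative_pd": c.cumulative_pd,
                    "density": c.densities,
                }
            )
        )
    long = pd.concat(frames)

    def _se(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) >= 2 else float("nan")

    agg = long.groupby("day").agg(
        mean_cumulative_pd=("cumulative_pd", "mean"),
        se_cumulative_pd=("cumulative_pd", _se),
        mean_density=("density", "mean"),
        se_density=("density", _se),
        n=("density", "size"),
    )
    return GenotypeSummary(
        genotype=curves[0].genotype,
        n_replicates=len(curves),
        table=agg.reset_index(),
    )
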
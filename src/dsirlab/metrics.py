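"""DSIR metrics, aggregation and cross-cutoff correlation.

A DSIR lower bound of ``x`` Hz means the range ``x``-8,000 Hz was required
in the HF ear; expressed as a percentage of the 0-8,000 Hz band this is
``(8000 - x) / 8000 * 100`` (e.g. a lower bound of 3,198 Hz is a
4,802-Hz-wide range, 60 % of the band).  Summaries report mean +- standard
error per design cell, excluding floored tracks (with their count
surfaced); the correlation analysis relates per-consonant percentages
between LPF-cutoff conditions with a Bonferroni-corrected alpha for the
three paired tests against the 250-Hz reference.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import BAND_TOP_HZ
from .tokens import ConsonantSpec, load_table

__all__ = [
    "pct_of_band",
    "invert_pct",
    "band_width",
    "summarize",
    "pearson_between_cutoffs",
    "correlation_table",
    "mean_table1_duration",
    "BONFERRONI_ALPHA",
]

#: Overall alpha 0.05 split over the three cutoff-pair correlation tests.
BONFERRONI_ALPHA = 0.05 / 3


def _check_range(value: float, lo: float, hi: float, name: str) -> None:
    if not (lo <= value <= hi):
        raise ValueError(f"{name} must lie in [{lo}, {hi}], got {value}")


def pct_of_band(dsir_low: float) -> float:
    """Percentage of the 0-8,000 Hz band above a DSIR lower bound."""
    _check_range(dsir_low, 0.0, BAND_TOP_HZ, "dsir_low")
    return (BAND_TOP_HZ - dsir_low) / BAND_TOP_HZ * 100.0


def invert_pct(pct: float) -> float:
    """DSIR lower bound (Hz) whose band covers ``pct`` % of 0-8,000 Hz."""
    _check_range(pct, 0.0, 100.0, "pct")
    return BAND_TOP_HZ * (1.0 - pct / 100.0)


def band_width(dsir_low: float) -> float:
    """Width in Hz of the required range ``dsir_low``-8,000 Hz."""
    _check_range(dsir_low, 0.0, BAND_TOP_HZ, "dsir_low")
    return BAND_TOP_HZ - dsir_low


def summarize(
    results: pd.DataFrame,
    by: Sequence[str] = ("condition", "lpf_cutoff"),
) -> tuple[pd.DataFrame, int]:
    """Aggregate track results into mean +- SE summary cells.

    Floored tracks are excluded from the statistics; the second return
    value is their count.  Raises ``ValueError`` on an empty table or when
    every track is floored.
    """
    if results.empty:
        raise ValueError("empty results table")
    n_floored = int(results["floored"].sum())
    converged = results[~results["floored"]]
    if converged.empty:
        raise ValueError("no converged tracks")
    grouped = converged.groupby(list(by))["dsir_low"]
    cells = grouped.agg(
        mean_dsir_low="mean",
        se_dsir_low=lambda x: x.sem(ddof=1) if len(x) > 1 else 0.0,
        n="count",
    ).reset_index()
    cells["mean_pct"] = cells["mean_dsir_low"].map(pct_of_band)
    cells["se_pct"] = cells["se_dsir_low"] / BAND_TOP_HZ * 100.0
    return cells, n_floored


def summarize_by_consonant(results: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Per-consonant summary cells (condition x LPF cutoff x consonant)."""
    return summarize(results, by=("condition", "lpf_cutoff", "consonant"))


def pearson_between_cutoffs(
    pct_a: Sequence[float], pct_b: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation between paired per-consonant percentages.

    Returns ``(r, p)``.  Raises on length mismatch or zero variance in
    either vector.
    """
    a = np.asarray(pct_a, dtype=float)
    b = np.asarray(pct_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and of equal length")
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def correlation_table(
    results: pd.DataFrame,
    reference_cutoff: int = 250,
) -> pd.DataFrame:
    """Cross-cutoff correlation of per-consonant DSIR percentages.

    For each processing condition, the per-consonant percentage (averaged
    over subjects) at the reference LPF cutoff is correlated against the
    same quantity at every other cutoff.  ``significant`` applies the
    Bonferroni-corrected alpha for the three tests sharing the reference.
    """
    converged = results[~results["floored"]]
    means = (
        converged.groupby(["condition", "lpf_cutoff", "consonant"])["pct_of_band"]
        .mean()
        .reset_index()
    )
    rows = []
    for condition, sub in means.groupby("condition"):
        wide = sub.pivot(index="consonant", columns="lpf_cutoff", values="pct_of_band")
        if reference_cutoff not in wide.columns:
            raise ValueError(f"reference cutoff {reference_cutoff} not in results")
        for cutoff in wide.columns:
            if cutoff == reference_cutoff:
                continue
            paired = wide[[reference_cutoff, cutoff]].dropna()
            r, p = pearson_between_cutoffs(
                paired[reference_cutoff], paired[cutoff]
            )
            rows.append({
                "condition": condition,
                "cutoff_a": reference_cutoff,
                "cutoff_b": int(cutoff),
                "r": r,
                "p": p,
                "alpha_bonferroni": BONFERRONI_ALPHA,
                "significant": p < BONFERRONI_ALPHA,
                "n": len(paired),
            })
    return pd.DataFrame(rows)


def mean_table1_duration(
    registry: Mapping[str, ConsonantSpec] | None = None,
) -> float:
    """Arithmetic mean of the tabulated consonant durations, ms."""
    registry = load_table() if registry is None else registry
    if not registry:
        raise ValueError("empty registry")
    durations = [spec.duration_ms for spec in registry.values()]
    return float(np.mean(durations))
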
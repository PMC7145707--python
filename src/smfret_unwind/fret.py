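"""FRET-efficiency analysis: E series, histograms, population classification,
and the unwound-fraction estimate.

For every molecule the apparent FRET efficiency is E = I_A / (I_D + I_A).
The first five data points of each molecule's E trace are pooled into a
condition-level histogram showing three characteristic populations: a
donor-only peak at E = 0, a low-FRET (unwound) population, and a high-FRET
(rewound) population.  The unwound fraction f_unwound is the low-FRET share
of the FRET-active sample, with a molecule-level bootstrap SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    FretSample,
    FretSeries,
    FUnwoundEstimate,
    PopulationCounts,
    TraceSet,
)

log = logging.getLogger(__name__)

__all__ = [
    "ClassificationThresholds",
    "compute_fret",
    "pool_first_k",
    "build_histogram",
    "classify",
    "estimate_f_unwound",
]

#: E clipping range applied for histogramming only (raw values are kept).
HISTOGRAM_CLIP = (-0.2, 1.2)

#: Published histograms of this assay pool at least this many molecules.
RECOMMENDED_MIN_MOLECULES = 2000


@dataclass(frozen=True)
class ClassificationThresholds:
    """Boundaries of the three E-histogram populations.

    E <= donor_only_max            -> donor-only
    donor_only_max < E < boundary  -> low FRET (unwound)
    E >= boundary                  -> high FRET (rewound)

    The customary boundary values are 0.6, 0.65 or 0.7; on well-separated
    histograms the choice barely moves f_unwound.  Values exactly at a
    threshold go to the class on its conservative side for f_unwound
    (donor_only_max -> donor-only, boundary -> high).
    """

    donor_only_max: float = 0.2
    low_high_boundary: float = 0.65

    def __post_init__(self) -> None:
        if not 0.0 < self.donor_only_max < self.low_high_boundary < 1.0:
            raise ValueError(
                "require 0 < donor_only_max < low_high_boundary < 1, got "
                f"{self.donor_only_max}, {self.low_high_boundary}"
            )


def compute_fret(
    i_d: np.ndarray,
    i_a: np.ndarray,
    total_floor: float | None = None,
    configured_total: float | None = None,
) -> FretSeries:
    """Elementwise E = I_A / (I_D + I_A) with a low-intensity validity floor.

    Frames whose total intensity I_D + I_A falls at or below the floor are
    marked invalid (E = NaN) rather than given a divide-by-small artifact.
    The floor defaults to 10% of ``configured_total`` when known, otherwise
    to the 5th percentile of the observed per-frame totals.
    """
    i_d = np.atleast_2d(np.asarray(i_d, dtype=float))
    i_a = np.atleast_2d(np.asarray(i_a, dtype=float))
    if i_d.shape != i_a.shape:
        raise ValueError(f"length mismatch: I_D {i_d.shape} vs I_A {i_a.shape}")
    total = i_d + i_a
    if total_floor is None:
        if configured_total is not None:
            total_floor = 0.10 * configured_total
        else:
            total_floor = float(np.percentile(total, 5.0))
    if total_floor <= 0:
        raise ValueError(f"total-intensity floor must be positive, got {total_floor}")
    valid = total > total_floor
    e = np.full_like(total, np.nan)
    np.divide(i_a, total, out=e, where=valid)
    return FretSeries(e=e, valid=valid, total_floor=float(total_floor))


def fret_from_traces(traces: TraceSet, **kwargs) -> FretSeries:
    """Convenience: :func:`compute_fret` on a TraceSet."""
    return compute_fret(traces.i_d, traces.i_a, **kwargs)


def pool_first_k(series: FretSeries, k: int = 5, label: str = "") -> FretSample:
    """Pool the first ``k`` valid frames of every molecule.

    Molecules with fewer than ``k`` valid frames contribute what they have.
    Logs a warning when fewer molecules than the published histogram scale
    (2000) are pooled.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if series.n_molecules == 0:
        raise ValueError("cannot pool an empty collection of traces")
    # rank of each valid frame within its molecule; keep ranks < k
    rank = np.cumsum(series.valid, axis=1) - 1
    take = series.valid & (rank < k)
    mol_idx, _ = np.nonzero(take)
    values = series.e[take]
    if series.n_molecules < RECOMMENDED_MIN_MOLECULES:
        log.warning(
            "E histogram pools only %d molecules; published histograms of this assay use more than %d",
            series.n_molecules,
            RECOMMENDED_MIN_MOLECULES,
        )
    return FretSample(
        label=label,
        values=values,
        molecule_index=mol_idx,
        n_molecules=series.n_molecules,
        k=k,
    )


def build_histogram(
    sample: FretSample,
    bin_width: float = 0.02,
    e_range: tuple[float, float] = (-0.1, 1.1),
) -> pd.DataFrame:
    """Half-open-bin E histogram with a density column summing to 1.

    Values are clipped to ``HISTOGRAM_CLIP`` first (raw sample unchanged);
    clipped values outside ``e_range`` do not enter any bin.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    if len(sample.values) == 0:
        raise ValueError("cannot histogram an empty sample")
    lo, hi = e_range
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    clipped = np.clip(sample.values, *HISTOGRAM_CLIP)
    # np.histogram closes the last bin on the right; emulate half-open bins
    counts, _ = np.histogram(clipped[clipped < edges[-1]], bins=edges)
    total = counts.sum()
    density = counts / total if total > 0 else counts.astype(float)
    return pd.DataFrame(
        {"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts, "density": density}
    )


def classify(
    sample: FretSample | np.ndarray, thresholds: ClassificationThresholds | None = None
) -> PopulationCounts:
    """Count pooled E values in the donor-only / low / high populations.

    The three counts always sum to the pooled sample size.
    """
    thresholds = thresholds or ClassificationThresholds()
    values = sample.values if isinstance(sample, FretSample) else np.asarray(sample, dtype=float)
    n_donor = int(np.count_nonzero(values <= thresholds.donor_only_max))
    n_high = int(np.count_nonzero(values >= thresholds.low_high_boundary))
    n_low = int(values.size - n_donor - n_high)
    return PopulationCounts(
        n_donor_only=n_donor,
        n_low=n_low,
        n_high=n_high,
        donor_only_max=thresholds.donor_only_max,
        low_high_boundary=thresholds.low_high_boundary,
    )


def _class_counts_per_molecule(
    sample: FretSample, thresholds: ClassificationThresholds
) -> np.ndarray:
    """(n_molecules, 3) per-molecule counts of donor-only / low / high frames."""
    v = sample.values
    cls = np.ones(v.shape, dtype=np.int64)  # low
    cls[v <= thresholds.donor_only_max] = 0
    cls[v >= thresholds.low_high_boundary] = 2
    counts = np.zeros((sample.n_molecules, 3), dtype=np.int64)
    np.add.at(counts, (sample.molecule_index, cls), 1)
    return counts


def _f_from_counts(counts: np.ndarray, include_donor_only: bool) -> float:
    n_donor, n_low, n_high = counts
    denom = n_low + n_high + (n_donor if include_donor_only else 0)
    if n_low + n_high == 0:
        raise ZeroDivisionError
    return n_low / denom


def estimate_f_unwound(
    series: FretSeries | FretSample,
    thresholds: ClassificationThresholds | None = None,
    k: int = 5,
    n_boot: int = 1000,
    seed=None,
    include_donor_only: bool = False,
    label: str = "",
) -> FUnwoundEstimate:
    """Unwound fraction of the pooled first-``k`` sample, with bootstrap SD.

    f_unwound = n_low / (n_low + n_high); the donor-only population is
    excluded from the denominator by default since those molecules carry no
    unwinding information (``include_donor_only=True`` switches convention).
    The SD resamples molecules -- not frames -- with replacement, because
    frames within a molecule are correlated.
    """
    thresholds = thresholds or ClassificationThresholds()
    if isinstance(series, FretSample):
        sample = series
    else:
        if series.n_molecules < 2:
            raise ValueError("need at least 2 molecules to estimate f_unwound")
        sample = pool_first_k(series, k=k, label=label)
    per_mol = _class_counts_per_molecule(sample, thresholds)
    totals = per_mol.sum(axis=0)
    pop = PopulationCounts(
        n_donor_only=int(totals[0]),
        n_low=int(totals[1]),
        n_high=int(totals[2]),
        donor_only_max=thresholds.donor_only_max,
        low_high_boundary=thresholds.low_high_boundary,
    )
    if pop.n_low + pop.n_high == 0:
        raise ValueError("no FRET-active molecules (low + high populations are empty)")
    f = _f_from_counts(totals, include_donor_only)

    low_mask = (sample.values > thresholds.donor_only_max) & (
        sample.values < thresholds.low_high_boundary
    )
    mean_e_low = float(sample.values[low_mask].mean()) if low_mask.any() else float("nan")

    rng = np.random.default_rng(seed)
    n_mol = per_mol.shape[0]
    boot = np.empty(n_boot)
    for b in range(n_boot):
        draw = per_mol[rng.integers(0, n_mol, size=n_mol)].sum(axis=0)
        try:
            boot[b] = _f_from_counts(draw, include_donor_only)
        except ZeroDivisionError:
            boot[b] = np.nan
    sd = float(np.nanstd(boot, ddof=1)) if n_boot > 1 else 0.0

    return FUnwoundEstimate(
        f_unwound=float(f),
        sd=sd,
        n_molecules=sample.n_molecules,
        mean_e_low=mean_e_low,
        counts=pop,
    )
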
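"""Shared data containers flowing between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REWOUND, UNWOUND = 0, 1
NO_BLEACH = -1


@dataclass
class GroundTruth:
    """Per-molecule simulation truth, used for parameter-recovery tests.

    All arrays are indexed by molecule.  Positions are (row, col) in
    half-image coordinates; trace-level simulations leave them as NaN.
    ``states`` holds 0 (rewound) / 1 (unwound) per frame; ``bleach_frame``
    is the first frame at which the acceptor is dark (-1 = never).
    """

    donor_only: np.ndarray
    bleach_frame: np.ndarray
    states: np.ndarray
    true_e: np.ndarray
    pos_acceptor: np.ndarray | None = None
    pos_donor: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.donor_only)
        if self.states.shape[0] != n or self.true_e.shape != self.states.shape:
            raise ValueError("ground-truth arrays disagree on n_molecules/n_frames")
        for pos in (self.pos_acceptor, self.pos_donor):
            if pos is not None and pos.shape != (n, 2):
                raise ValueError("position arrays must be (n_molecules, 2)")

    @property
    def n_molecules(self) -> int:
        return len(self.donor_only)

    @property
    def n_frames(self) -> int:
        return self.states.shape[1]

    def molecule_frame(self) -> pd.DataFrame:
        """One row per molecule (positions, flags, bleach frame)."""
        d = {
            "molecule_id": np.arange(self.n_molecules),
            "donor_only": self.donor_only.astype(int),
            "bleach_frame": self.bleach_frame,
        }
        if self.pos_acceptor is not None:
            d["row_acceptor"] = self.pos_acceptor[:, 0]
            d["col_acceptor"] = self.pos_acceptor[:, 1]
        if self.pos_donor is not None:
            d["row_donor"] = self.pos_donor[:, 0]
            d["col_donor"] = self.pos_donor[:, 1]
        return pd.DataFrame(d)

    def state_frame(self) -> pd.DataFrame:
        """Long-form per-frame state and true E."""
        n, t = self.states.shape
        return pd.DataFrame(
            {
                "molecule_id": np.repeat(np.arange(n), t),
                "frame": np.tile(np.arange(t), n),
                "state": self.states.ravel(),
                "true_e": self.true_e.ravel(),
            }
        )

    def unwound_fraction(self, first_k: int | None = None, exclude_donor_only: bool = True) -> float:
        """Realized unwound occupancy over (the first k) frames."""
        states = self.states
        if exclude_donor_only:
            states = states[~self.donor_only]
        if first_k is not None:
            states = states[:, :first_k]
        return float(np.mean(states == UNWOUND))


@dataclass
class TraceSet:
    """Background-corrected donor/acceptor intensity traces.

    ``i_d`` and ``i_a`` are (n_molecules, n_frames) arrays in counts/frame;
    values may be slightly negative after background subtraction.
    """

    i_d: np.ndarray
    i_a: np.ndarray
    frame_interval: float
    molecule_ids: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.i_d = np.asarray(self.i_d, dtype=float)
        self.i_a = np.asarray(self.i_a, dtype=float)
        if self.i_d.shape != self.i_a.shape or self.i_d.ndim != 2:
            raise ValueError("i_d and i_a must be equal-shape 2-D arrays")
        if not (np.isfinite(self.i_d).all() and np.isfinite(self.i_a).all()):
            raise ValueError("traces must be finite")
        if self.molecule_ids is None:
            self.molecule_ids = np.arange(self.i_d.shape[0])
        self.molecule_ids = np.asarray(self.molecule_ids)

    @property
    def n_molecules(self) -> int:
        return self.i_d.shape[0]

    @property
    def n_frames(self) -> int:
        return self.i_d.shape[1]

    def to_frame(self) -> pd.DataFrame:
        n, t = self.i_d.shape
        return pd.DataFrame(
            {
                "molecule_id": np.repeat(self.molecule_ids, t),
                "frame": np.tile(np.arange(t), n),
                "I_D": self.i_d.ravel(),
                "I_A": self.i_a.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, frame_interval: float, **kwargs) -> "TraceSet":
        wide_d = df.pivot(index="molecule_id", columns="frame", values="I_D").sort_index()
        wide_a = df.pivot(index="molecule_id", columns="frame", values="I_A").sort_index()
        return cls(
            i_d=wide_d.to_numpy(),
            i_a=wide_a.to_numpy(),
            frame_interval=frame_interval,
            molecule_ids=wide_d.index.to_numpy(),
            **kwargs,
        )


@dataclass
class SpotTable:
    """Detected acceptor-channel spots with mapped donor-half coordinates.

    ``table`` columns: spot_id, row_acceptor, col_acceptor (sub-pixel,
    acceptor-half frame), quality, and after registration row_donor,
    col_donor, in_bounds.
    """

    table: pd.DataFrame
    half_width: int

    REQUIRED = ("spot_id", "row_acceptor", "col_acceptor", "quality")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"SpotTable missing column {col!r}")
        if len(self.table) and (self.table["col_acceptor"] >= self.half_width).any():
            raise ValueError("acceptor columns must be < half width (half-local coordinates)")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class FretSeries:
    """Per-molecule FRET efficiency time series with a validity mask.

    ``e`` holds the raw ratio I_A/(I_D+I_A); frames whose total intensity
    fell below the low-intensity floor are invalid (mask False, e = NaN).
    """

    e: np.ndarray
    valid: np.ndarray
    total_floor: float

    def __post_init__(self) -> None:
        if self.e.shape != self.valid.shape or self.e.ndim != 2:
            raise ValueError("e and valid must be equal-shape 2-D arrays")

    @property
    def n_molecules(self) -> int:
        return self.e.shape[0]


@dataclass
class FretSample:
    """Pooled per-molecule E values (first k valid frames each) for one condition."""

    label: str
    values: np.ndarray
    molecule_index: np.ndarray
    n_molecules: int
    k: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.molecule_index = np.asarray(self.molecule_index)
        if self.values.shape != self.molecule_index.shape:
            raise ValueError("values and molecule_index must align")
        if len(self.values) > self.k * self.n_molecules:
            raise ValueError("pooled count exceeds k * n_molecules")


@dataclass(frozen=True)
class PopulationCounts:
    """Molecule-frame counts in the donor-only / low-FRET / high-FRET classes."""

    n_donor_only: int
    n_low: int
    n_high: int
    donor_only_max: float
    low_high_boundary: float

    @property
    def total(self) -> int:
        return self.n_donor_only + self.n_low + self.n_high


@dataclass(frozen=True)
class FUnwoundEstimate:
    """Unwound fraction for one condition, with bootstrap uncertainty.

    ``f_unwound`` is the low-FRET share of the FRET-active (low+high)
    pooled sample; ``sd`` is the molecule-level bootstrap SD.
    ``mean_e_low`` is the mean E of the low-FRET (unwound) population.
    """

    f_unwound: float
    sd: float
    n_molecules: int
    mean_e_low: float
    counts: PopulationCounts | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_unwound <= 1.0:
            raise ValueError(f"f_unwound must be in [0, 1], got {self.f_unwound}")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


#: gRNA designs whose spacer is 5'-truncated; promiscuity and S are not
#: defined for them (they cannot pair the full 20-nt protospacer).
TRUNCATED_GRNAS = frozenset({"X18", "gX18", "X17"})
GRNA_DESIGNS = ("X20", "gX20", "ggX20", "X18", "gX18", "X17")


@dataclass
class MismatchProfile:
    """f_unwound estimates across n_PD for one Cas9 x gRNA combination."""

    label: str
    estimates: dict[int, FUnwoundEstimate]
    grna: str = "X20"

    def __post_init__(self) -> None:
        for n_pd in self.estimates:
            if n_pd not in (0, 1, 2, 3, 4):
                raise ValueError(f"n_PD must be in 0..4, got {n_pd}")

    @property
    def is_truncated(self) -> bool:
        return self.grna in TRUNCATED_GRNAS

    def require(self, n_pds: tuple[int, ...]) -> None:
        missing = [n for n in n_pds if n not in self.estimates]
        if missing:
            raise KeyError(
                f"profile {self.label!r} lacks n_PD {missing}; cannot compute the statistic"
            )


@dataclass(frozen=True)
class SpecificityResult:
    """On-target activity, promiscuity and specificity S for one condition.

    S = f_unwound(0) / sum_{n=1..3} n * f_unwound(n); None when the gRNA is
    truncated (S undefined by construction).
    """

    label: str
    grna: str
    on_target: float
    on_target_sd: float
    promiscuity: float
    promiscuity_sd: float
    s: float | None
    sd_s: float | None
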
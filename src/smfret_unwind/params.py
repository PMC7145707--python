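"""Parameter containers for the smFRET unwinding simulator and pipeline.

The simulated system is a surface-immobilized Cas9-RNA-DNA complex that
interconverts between a *rewound* (duplex reformed, high FRET) and an
*unwound* (R-loop open, low FRET) conformation.  Kinetics are a two-state
continuous-time Markov chain; photophysics map the conformational state to
donor/acceptor emission.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

#: Placeholder exchange rate (k_open + k_close, s^-1) used when only the
#: equilibrium occupancy is supplied.  The unwound/rewound dwell times have
#: not been measured; this default is deliberately slow compared to the
#: 35-100 ms frame times so that the first few frames of a trace sample a
#: quasi-static conformation, consistent with E histograms that resolve two
#: distinct populations.
DEFAULT_EXCHANGE_RATE = 0.2

#: Frame intervals (seconds) used by the imaging experiments.
STANDARD_FRAME_INTERVALS = (0.100, 0.035)

VALID_N_PD = (0, 1, 2, 3, 4)


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class KineticParams:
    """Two-state rewound <-> unwound exchange.

    Parameters
    ----------
    p_unwound:
        Equilibrium occupancy of the unwound state, in [0, 1].
    k_open, k_close:
        Optional rewound->unwound and unwound->rewound rates (s^-1).  When
        both are given they must satisfy
        ``p_unwound == k_open / (k_open + k_close)`` to within 1e-12.
        When omitted, rates are derived from ``p_unwound`` and
        :data:`DEFAULT_EXCHANGE_RATE`.
    """

    p_unwound: float
    k_open: float | None = None
    k_close: float | None = None

    def __post_init__(self) -> None:
        p = _require_finite("p_unwound", self.p_unwound)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p_unwound must be in [0, 1], got {p}")
        object.__setattr__(self, "p_unwound", p)
        if (self.k_open is None) != (self.k_close is None):
            raise ValueError("k_open and k_close must be supplied together")
        if self.k_open is not None:
            ko = _require_finite("k_open", self.k_open)
            kc = _require_finite("k_close", self.k_close)
            if ko < 0:
                raise ValueError(f"k_open must be >= 0, got {ko}")
            if kc < 0:
                raise ValueError(f"k_close must be >= 0, got {kc}")
            object.__setattr__(self, "k_open", ko)
            object.__setattr__(self, "k_close", kc)
            total = ko + kc
            implied = ko / total if total > 0 else p
            if abs(implied - p) > 1e-12:
                raise ValueError(
                    f"inconsistent kinetics: k_open/(k_open+k_close)={implied!r} "
                    f"but p_unwound={p!r}"
                )

    @classmethod
    def from_rates(cls, k_open: float, k_close: float) -> "KineticParams":
        """Build from rates alone; occupancy follows from detailed balance."""
        total = float(k_open) + float(k_close)
        p = float(k_open) / total if total > 0 else 0.0
        return cls(p_unwound=p, k_open=float(k_open), k_close=float(k_close))

    @classmethod
    def from_occupancy(
        cls, p_unwound: float, exchange_rate: float = DEFAULT_EXCHANGE_RATE
    ) -> "KineticParams":
        """Build from equilibrium occupancy and a total exchange rate."""
        p = float(p_unwound)
        return cls(p_unwound=p, k_open=p * exchange_rate, k_close=(1.0 - p) * exchange_rate)

    @property
    def rates(self) -> tuple[float, float]:
        """(k_open, k_close), deriving defaults from occupancy when absent."""
        if self.k_open is not None:
            return self.k_open, self.k_close  # type: ignore[return-value]
        p = self.p_unwound
        return p * DEFAULT_EXCHANGE_RATE, (1.0 - p) * DEFAULT_EXCHANGE_RATE

    def to_dict(self) -> dict:
        return {"p_unwound": self.p_unwound, "k_open": self.k_open, "k_close": self.k_close}

    @classmethod
    def from_dict(cls, d: Mapping) -> "KineticParams":
        return cls(**dict(d))


@dataclass(frozen=True)
class PhotophysicsParams:
    """Maps conformational state to donor/acceptor emission.

    Expected channel intensities for a molecule in state ``s`` (FRET
    efficiency ``E_s``) before noise are::

        I_A = E_s * total_intensity + background
        I_D = (1 - E_s) * total_intensity + background

    A donor-only molecule (missing or inactive acceptor) emits everything
    in the donor channel (true E = 0).  ``bleach_rate`` is the per-frame
    probability of single-step acceptor photobleaching; a bleached acceptor
    turns the molecule donor-only for the rest of the trace.
    """

    e_rewound: float = 0.75
    e_unwound: float = 0.30
    total_intensity: float = 500.0
    noise_sd: float = 25.0
    background: float = 0.0
    donor_only_fraction: float = 0.10
    bleach_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.e_rewound <= 1.0:
            raise ValueError(f"e_rewound must be in (0, 1], got {self.e_rewound}")
        if not 0.0 <= self.e_unwound < 1.0:
            raise ValueError(f"e_unwound must be in [0, 1), got {self.e_unwound}")
        if self.e_unwound >= self.e_rewound:
            raise ValueError(
                f"e_unwound ({self.e_unwound}) must be below e_rewound ({self.e_rewound})"
            )
        if self.total_intensity <= 0:
            raise ValueError(f"total_intensity must be > 0, got {self.total_intensity}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.background < 0:
            raise ValueError(f"background must be >= 0, got {self.background}")
        if not 0.0 <= self.donor_only_fraction < 1.0:
            raise ValueError(
                f"donor_only_fraction must be in [0, 1), got {self.donor_only_fraction}"
            )
        if not 0.0 <= self.bleach_rate < 1.0:
            raise ValueError(f"bleach_rate must be in [0, 1), got {self.bleach_rate}")

    def fret_sd(self, e_state: float | None = None) -> float:
        """Approximate per-frame SD of measured E for a state at ``e_state``.

        First-order propagation of independent per-channel Gaussian noise
        through E = I_A/(I_A+I_D) at zero background.
        """
        e = 0.5 if e_state is None else float(e_state)
        return (
            self.noise_sd
            * math.sqrt((1.0 - e) ** 2 + e**2)
            / self.total_intensity
        )

    @classmethod
    def with_fret_sd(cls, target_sd: float, e_state: float = 0.75, **kwargs) -> "PhotophysicsParams":
        """Choose ``noise_sd`` so the per-frame E SD at ``e_state`` is ``target_sd``."""
        base = cls(noise_sd=0.0, **kwargs)
        noise = (
            float(target_sd)
            * base.total_intensity
            / math.sqrt((1.0 - e_state) ** 2 + e_state**2)
        )
        return cls(noise_sd=noise, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PhotophysicsParams":
        return cls(**dict(d))


@dataclass(frozen=True)
class MovieParams:
    """Geometry and camera model of the rendered dual-channel movie.

    The donor emission occupies columns ``[0, width/2)`` and the acceptor
    emission ``[width/2, width)`` of each frame (0-based, half-open), as on
    an EMCCD whose two halves receive the split optical paths.
    ``channel_offset`` is the (dx, dy) sub-pixel translation taking
    acceptor-half coordinates to donor-half coordinates.
    """

    n_frames: int = 10
    frame_interval: float = 0.100
    height: int = 220
    width: int = 440
    psf_sigma: float = 1.2
    n_molecules: int = 100
    channel_offset: tuple[float, float] = (0.0, 0.0)
    camera_baseline: float = 100.0
    camera_gain_noise_sd: float = 3.0
    min_separation_factor: float = 6.0
    border_margin_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.width % 2 != 0:
            raise ValueError(f"width must be even (two camera halves), got {self.width}")
        if self.height < 1 or self.width < 2:
            raise ValueError("height and width must be positive")
        if self.psf_sigma <= 0:
            raise ValueError(f"psf_sigma must be > 0, got {self.psf_sigma}")
        if self.n_molecules < 0:
            raise ValueError(f"n_molecules must be >= 0, got {self.n_molecules}")
        if self.frame_interval <= 0:
            raise ValueError(f"frame_interval must be > 0, got {self.frame_interval}")
        if self.camera_baseline < 0 or self.camera_gain_noise_sd < 0:
            raise ValueError("camera_baseline and camera_gain_noise_sd must be >= 0")
        object.__setattr__(self, "channel_offset", tuple(float(v) for v in self.channel_offset))

    @property
    def half_width(self) -> int:
        return self.width // 2

    @property
    def min_separation(self) -> float:
        """Minimum allowed spot separation (pixels)."""
        return self.min_separation_factor * self.psf_sigma

    @property
    def border_margin(self) -> float:
        """Minimum distance of molecule centers from half-image borders."""
        return self.border_margin_factor * self.psf_sigma

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channel_offset"] = list(self.channel_offset)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "MovieParams":
        d = dict(d)
        if "channel_offset" in d:
            d["channel_offset"] = tuple(d["channel_offset"])
        return cls(**d)


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition: Cas9 variant x gRNA design x n_PD.

    ``n_pd`` is the number of PAM-distal base-pair mismatches between the
    gRNA spacer and the protospacer (0 = cognate DNA).
    """

    label: str
    n_pd: int
    kinetics: KineticParams
    photophysics: PhotophysicsParams = field(default_factory=PhotophysicsParams)
    grna: str = "X20"

    def __post_init__(self) -> None:
        if self.n_pd not in VALID_N_PD:
            raise ValueError(f"n_pd must be one of {VALID_N_PD}, got {self.n_pd}")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_pd": self.n_pd,
            "grna": self.grna,
            "kinetics": self.kinetics.to_dict(),
            "photophysics": self.photophysics.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ConditionSpec":
        d = dict(d)
        d["kinetics"] = KineticParams.from_dict(d["kinetics"])
        if "photophysics" in d:
            d["photophysics"] = PhotophysicsParams.from_dict(d["photophysics"])
        return cls(**d)
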
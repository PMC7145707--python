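"""Ground-truth-labeled synthetic smFRET data.

Three levels of synthesis, each feeding the next pipeline stage:

1. :func:`simulate_state_trajectory` -- two-state (rewound <-> unwound)
   Markov-chain conformational trajectories sampled at the frame times.
2. :func:`simulate_trace_set` -- noisy donor/acceptor intensity traces for
   a population of immobilized molecules, including a donor-only
   subpopulation and optional acceptor photobleaching.
3. :func:`render_movie` -- a dual-channel 16-bit movie stack in which each
   molecule is a Gaussian point-spread function on the two camera halves.

Every simulated object is paired with a :class:`~.containers.GroundTruth`
record so downstream estimates can be checked against the truth.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
from scipy.special import erf

from .containers import NO_BLEACH, REWOUND, UNWOUND, GroundTruth, TraceSet
from .params import ConditionSpec, KineticParams, MovieParams, PhotophysicsParams

__all__ = [
    "simulate_state_trajectory",
    "simulate_trace_set",
    "render_movie",
    "make_condition_panel",
    "pixel_integrated_psf",
    "add_spot",
]


def _rng_from(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _child_rngs(seed, n: int) -> list[np.random.Generator]:
    """Deterministic per-stage substreams from one top-level seed."""
    if isinstance(seed, np.random.Generator):
        ss = seed.bit_generator.seed_seq  # type: ignore[attr-defined]
    else:
        ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def transition_probabilities(kin: KineticParams, dt: float) -> tuple[float, float]:
    """Exact discrete-time transition probabilities over one frame.

    For the two-state chain with generator rates (k_open, k_close) and
    stationary unwound occupancy p = k_open/(k_open+k_close), the matrix
    exponential gives in closed form::

        P(unwound at t+dt | rewound at t) = p * (1 - exp(-k*dt))
        P(unwound at t+dt | unwound at t) = p + (1 - p) * exp(-k*dt)

    with k = k_open + k_close.

    Returns
    -------
    (p_ru, p_uu):
        Probability of being unwound after ``dt`` given rewound / unwound now.
    """
    k_open, k_close = kin.rates
    k = k_open + k_close
    if k == 0.0:
        return 0.0, 1.0  # frozen chain: stay wherever you are
    decay = math.exp(-k * dt)
    p = k_open / k
    return p * (1.0 - decay), p + (1.0 - p) * decay


def _simulate_states(
    kin: KineticParams, n_molecules: int, n_frames: int, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized state matrix (n_molecules, n_frames) of 0/1."""
    p_ru, p_uu = transition_probabilities(kin, dt)
    states = np.empty((n_molecules, n_frames), dtype=np.uint8)
    current = (rng.random(n_molecules) < kin.p_unwound).astype(np.uint8)
    states[:, 0] = current
    for t in range(1, n_frames):
        p_next = np.where(current == UNWOUND, p_uu, p_ru)
        current = (rng.random(n_molecules) < p_next).astype(np.uint8)
        states[:, t] = current
    return states


def simulate_state_trajectory(
    kin: KineticParams, n_frames: int, frame_interval: float, seed=None
) -> np.ndarray:
    """Sample one conformational trajectory at the camera frame times.

    The initial state is drawn from the stationary distribution
    (unwound with probability ``p_unwound``); subsequent frames use the
    exact discretization of the continuous-time two-state chain.

    Returns an array of 0 (rewound) / 1 (unwound) of length ``n_frames``.
    """
    if n_frames < 1:
        raise ValueError(f"n_frames must be >= 1, got {n_frames}")
    if frame_interval <= 0:
        raise ValueError(f"frame_interval must be > 0, got {frame_interval}")
    rng = _rng_from(seed)
    return _simulate_states(kin, 1, n_frames, frame_interval, rng)[0]


def _simulate_ground_truth(
    cond: ConditionSpec,
    n_molecules: int,
    n_frames: int,
    frame_interval: float,
    rng_labels: np.random.Generator,
    rng_states: np.random.Generator,
) -> GroundTruth:
    phot = cond.photophysics
    donor_only = rng_labels.random(n_molecules) < phot.donor_only_fraction
    if phot.bleach_rate > 0.0:
        # geometric first-dark frame; frame 0 is always lit
        bleach = rng_labels.geometric(phot.bleach_rate, size=n_molecules)
        bleach = np.where(bleach >= n_frames, NO_BLEACH, bleach).astype(np.int64)
    else:
        bleach = np.full(n_molecules, NO_BLEACH, dtype=np.int64)
    states = _simulate_states(cond.kinetics, n_molecules, n_frames, frame_interval, rng_states)

    true_e = np.where(states == UNWOUND, phot.e_unwound, phot.e_rewound)
    frames = np.arange(n_frames)
    acceptor_dark = donor_only[:, None] | (
        (bleach[:, None] != NO_BLEACH) & (frames[None, :] >= bleach[:, None])
    )
    true_e = np.where(acceptor_dark, 0.0, true_e)
    return GroundTruth(
        donor_only=donor_only, bleach_frame=bleach, states=states, true_e=true_e
    )


def simulate_trace_set(
    cond: ConditionSpec,
    n_molecules: int,
    n_frames: int,
    frame_interval: float = 0.100,
    seed=None,
) -> tuple[TraceSet, GroundTruth]:
    """Simulate noisy donor/acceptor traces for a molecule population.

    Per molecule: a donor-only flag, a conformational trajectory, an
    acceptor bleach frame, and per-frame channel intensities::

        I_A = E_eff * total_intensity + background + N(0, noise_sd)
        I_D = (1 - E_eff) * total_intensity + background + N(0, noise_sd)

    where ``E_eff`` is the state's FRET efficiency, forced to 0 for
    donor-only molecules and for frames at/after acceptor bleaching (the
    donor then carries the full emission).  Deterministic given ``seed``.
    """
    if n_molecules < 1:
        raise ValueError(f"n_molecules must be >= 1, got {n_molecules}")
    rng_labels, rng_states, rng_noise = _child_rngs(seed, 3)
    gt = _simulate_ground_truth(
        cond, n_molecules, n_frames, frame_interval, rng_labels, rng_states
    )
    phot = cond.photophysics
    mean_a = gt.true_e * phot.total_intensity + phot.background
    mean_d = (1.0 - gt.true_e) * phot.total_intensity + phot.background
    if phot.noise_sd > 0:
        i_a = mean_a + rng_noise.normal(0.0, phot.noise_sd, size=mean_a.shape)
        i_d = mean_d + rng_noise.normal(0.0, phot.noise_sd, size=mean_d.shape)
    else:
        i_a, i_d = mean_a, mean_d
    traces = TraceSet(
        i_d=i_d,
        i_a=i_a,
        frame_interval=frame_interval,
        provenance={"source": "simulate_trace_set", "condition": cond.label, "n_pd": cond.n_pd},
    )
    return traces, gt


# ---------------------------------------------------------------------------
# movie rendering


def pixel_integrated_psf(
    center: tuple[float, float], sigma: float, rows: np.ndarray, cols: np.ndarray
) -> np.ndarray:
    """Unit-mass 2-D Gaussian integrated over unit pixels.

    ``rows``/``cols`` are integer pixel indices; the returned array has
    shape (len(rows), len(cols)) and sums to 1 over an infinite grid.
    """
    s = sigma * math.sqrt(2.0)
    r0, c0 = center
    fr = 0.5 * (erf((rows + 0.5 - r0) / s) - erf((rows - 0.5 - r0) / s))
    fc = 0.5 * (erf((cols + 0.5 - c0) / s) - erf((cols - 0.5 - c0) / s))
    return np.outer(fr, fc)


def add_spot(
    image: np.ndarray, center: tuple[float, float], sigma: float, amplitude: float
) -> None:
    """Add a Gaussian spot of integrated ``amplitude`` counts in place."""
    h, w = image.shape
    r0, c0 = center
    half = max(3, int(math.ceil(4.5 * sigma)))
    r_lo, r_hi = max(0, int(round(r0)) - half), min(h, int(round(r0)) + half + 1)
    c_lo, c_hi = max(0, int(round(c0)) - half), min(w, int(round(c0)) + half + 1)
    if r_lo >= r_hi or c_lo >= c_hi:
        return
    rows = np.arange(r_lo, r_hi)
    cols = np.arange(c_lo, c_hi)
    image[r_lo:r_hi, c_lo:c_hi] += amplitude * pixel_integrated_psf(center, sigma, rows, cols)


def _place_molecules(params: MovieParams, rng: np.random.Generator) -> np.ndarray:
    """Random acceptor-half positions with margin and minimum separation.

    Greedy rejection sampling; raises when the requested density cannot be
    placed (overlapping spots would violate the extraction model).
    """
    n = params.n_molecules
    if n == 0:
        return np.empty((0, 2))
    hw, h = params.half_width, params.height
    margin = params.border_margin
    dx, dy = params.channel_offset
    # keep both the acceptor spot and its donor image inside their halves
    row_lo = margin + max(0.0, -dy)
    row_hi = h - 1 - margin - max(0.0, dy)
    col_lo = margin + max(0.0, -dx)
    col_hi = hw - 1 - margin - max(0.0, dx)
    if row_hi <= row_lo or col_hi <= col_lo:
        raise ValueError("image too small for the border margin and channel offset")
    min_sep2 = params.min_separation**2
    placed: list[np.ndarray] = []
    attempts, max_attempts = 0, 2000 + 400 * n
    while len(placed) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"cannot place {n} molecules with minimum separation "
                f"{params.min_separation:.1f} px in a {h}x{hw} half-image; "
                "overlapping spots violate the extraction model"
            )
        cand = np.array(
            [rng.uniform(row_lo, row_hi), rng.uniform(col_lo, col_hi)]
        )
        if all(np.sum((cand - p) ** 2) >= min_sep2 for p in placed):
            placed.append(cand)
    return np.array(placed)


def render_movie(
    params: MovieParams, cond: ConditionSpec, seed=None
) -> tuple[np.ndarray, GroundTruth]:
    """Render a dual-channel movie stack for one condition.

    Each molecule is a 2-D Gaussian PSF whose integrated amplitude per
    frame equals its channel intensity, placed at its acceptor-half
    position (right half) and at the offset-mapped donor-half position
    (left half).  Per-pixel camera baseline and Gaussian read noise are
    added, and values are clipped to the unsigned 16-bit range.

    Returns
    -------
    (stack, ground_truth):
        ``stack`` is (n_frames, height, width) uint16; ``ground_truth``
        carries positions in half-local coordinates.
    """
    rng_place, rng_labels, rng_states, rng_signal, rng_camera = _child_rngs(seed, 5)
    positions = _place_molecules(params, rng_place)
    gt = _simulate_ground_truth(
        cond, params.n_molecules, params.n_frames, params.frame_interval, rng_labels, rng_states
    )
    dx, dy = params.channel_offset
    gt.pos_acceptor = positions
    gt.pos_donor = positions + np.array([dy, dx])

    phot = cond.photophysics
    mean_a = gt.true_e * phot.total_intensity
    mean_d = (1.0 - gt.true_e) * phot.total_intensity
    if phot.noise_sd > 0 and params.n_molecules > 0:
        amp_a = mean_a + rng_signal.normal(0.0, phot.noise_sd, size=mean_a.shape)
        amp_d = mean_d + rng_signal.normal(0.0, phot.noise_sd, size=mean_d.shape)
    else:
        amp_a, amp_d = mean_a, mean_d

    h, w, hw = params.height, params.width, params.half_width
    stack = np.empty((params.n_frames, h, w), dtype=np.uint16)
    sigma = params.psf_sigma
    for t in range(params.n_frames):
        frame = np.full((h, w), float(params.camera_baseline))
        for m in range(params.n_molecules):
            r, c = positions[m]
            add_spot(frame[:, hw:], (r, c), sigma, amp_a[m, t])
            add_spot(frame[:, :hw], (r + dy, c + dx), sigma, amp_d[m, t])
        if params.camera_gain_noise_sd > 0:
            frame += rng_camera.normal(0.0, params.camera_gain_noise_sd, size=frame.shape)
        stack[t] = np.clip(np.rint(frame), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return stack, gt


def make_condition_panel(
    profile: Mapping[int, float],
    photophysics: PhotophysicsParams | None = None,
    label: str = "condition",
    grna: str = "X20",
    exchange_rate: float | None = None,
) -> list[ConditionSpec]:
    """One ConditionSpec per n_PD with the stated equilibrium occupancies.

    ``profile`` maps n_PD (0..4) to the unwound-state occupancy p_unwound;
    all conditions share the same photophysics.
    """
    phot = photophysics if photophysics is not None else PhotophysicsParams()
    panel = []
    for n_pd in sorted(profile):
        p = profile[n_pd]
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"occupancy for n_PD={n_pd} must be in [0, 1], got {p}")
        if exchange_rate is not None:
            kin = KineticParams.from_occupancy(p, exchange_rate)
        else:
            kin = KineticParams(p_unwound=p)
        panel.append(
            ConditionSpec(label=label, n_pd=n_pd, kinetics=kin, photophysics=phot, grna=grna)
        )
    return panel
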
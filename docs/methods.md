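# Methods

## The measurement being modeled

A surface-immobilized DNA target carries a donor (Cy3) and an acceptor
(Cy5) dye 9 bp apart.  Free DNA and the rewound Cas9-RNA-DNA complex show
high FRET (E ≈ 0.75); Cas9-RNA-induced unwinding of the PAM-distal
protospacer separates the dyes and lowers E to ≈ 0.3.  Movies are recorded
on an EMCCD whose two halves receive the donor and acceptor emission paths
(frame time 100 or 35 ms).  The catalytically dead Cas9 variants used in
these assays bind and unwind but never cleave, so each molecule sits in a
two-state rewound ⇌ unwound equilibrium whose unwound occupancy is the
quantity of interest.

## Two-state kinetic model

The conformational dynamics are a continuous-time Markov chain with rates
k_open (rewound→unwound) and k_close (unwound→rewound) and stationary
unwound occupancy p = k_open/(k_open + k_close).  Trajectories are sampled
at the frame times using the exact discretization (matrix exponential of
the 2×2 generator, closed form):

    P(unwound at t+Δ | rewound) = p · (1 − e^{−kΔ}),   k = k_open + k_close
    P(unwound at t+Δ | unwound) = p + (1 − p) · e^{−kΔ}

The initial state is drawn from the stationary distribution.  The dwell
times of the exchange have not been measured; the simulator is therefore
parameterized primarily by the occupancy p, with an optional explicit rate
pair.  When only p is given, rates default to a total exchange rate of
0.2 s⁻¹ (mean dwell ≈ 5 s) — a placeholder, deliberately slow relative to
the 0.1 s frames so that the first five data points of a trace sample a
quasi-static conformation, which is what E histograms resolving two
distinct populations imply.  This default is flagged as a placeholder in
the parameter documentation; any analysis sensitive to within-trace
dynamics should set rates explicitly.

The discretization is validated against an independent event-driven
(Gillespie) simulation of the same chain: long-run occupancies agree, and
frame-to-frame transition-count tables from the two simulators pass a
chi-squared homogeneity test over >10⁴ transitions.

## Photophysics and noise

A molecule in a state with FRET efficiency E_s emits, per frame and before
noise,

    I_A = E_s · T + b,    I_D = (1 − E_s) · T + b

with total emission T (default 500 counts/frame) and per-channel background
b (default 0 at trace level; movies carry background as a per-pixel camera
baseline instead).  Channel noise is additive Gaussian with SD σ (default
25 counts/frame), approximating EMCCD excess noise at these count levels
and keeping the induced E broadening interpretable: first-order propagation
gives a per-frame E SD of σ·sqrt((1−E)² + E²)/T, ≈ 0.04 at the defaults
near the high-FRET state.  That width is typical of well-separated smFRET
histogram peaks; `PhotophysicsParams.with_fret_sd` inverts the relation
when a specific broadening is wanted.  Poisson shot noise, Cy3/Cy5
blinking, spectral crosstalk and gamma correction are deliberately not
modeled.

A fraction of molecules (default 10%) is donor-only — the acceptor is
missing or inactive — and emits everything in the donor channel (true
E = 0), reproducing the E ≈ 0 peak of measured histograms.  Optional
acceptor photobleaching is single-step with a per-frame probability; after
the bleach frame the molecule behaves donor-only (I_A at background, the
donor carrying the full emission).  This acceptor-first convention was
chosen over killing both channels because it matches the observed behavior
of Cy5 under smFRET imaging and produces the donor-rise signature that the
extraction tests check.

## Movie rendering

Each molecule is a 2-D Gaussian PSF (default σ = 1.2 px) whose *integrated*
amplitude per frame equals the channel intensity; pixels receive the
Gaussian integrated over their unit area (erf differences), the camera adds
a per-pixel baseline and Gaussian read noise, and values are rounded and
clipped to 16-bit.  Donor and acceptor images of a molecule are related by
a pure sub-pixel translation (registration is assumed known; affine
registration is out of scope).  Placement is uniform within each half with
a 3σ border margin and a minimum center-to-center separation of 6σ,
enforced by rejection sampling; a density that cannot be placed is an
error, because overlapping spots violate the photometry model.

## Spot detection and photometry

Detection runs on the time-average of the first ≤20 frames of the
*acceptor* channel only — implementing the stated exclusion of molecules
without an active acceptor.  The average is band-pass filtered with a
difference of Gaussians (0.67·σ_psf and 2·σ_psf; the narrow scale is kept
below the PSF so that two spots near the separation limit remain resolved
rather than merging into one detection), thresholded at
median + k·(1.4826·MAD) with k = 6 (the MAD is scaled to a consistent
robust σ), local maxima are refined to sub-pixel centroids in a 7×7 window,
and any spot with a neighbor closer than the minimum separation is dropped
together with that neighbor.  In the pipeline the detection separation is
set 0.5 px below the rendering minimum so centroid noise on legitimately
spaced pairs does not discard them.

Photometry sums a circular aperture (radius 3.5 px) and subtracts the
median of a 5–8 px annulus times the aperture area, per frame and channel.
Spots whose annulus leaves the image are excluded with a logged reason.  At
the default σ_psf = 1.2 the aperture captures ≈ 98% of the PSF mass; this
truncation is common mode between the channels and cancels in the E ratio,
so no aperture correction is applied.  Donor-only molecules can still leak
into the spot table through noise; they are handled again at
classification, which is why measured histograms keep an E = 0 peak.

## E histograms, classification, f_unwound

E = I_A/(I_D + I_A) per frame; frames whose total falls at or below a floor
(10% of the configured total emission, or the 5th percentile of observed
totals when unconfigured) are marked invalid rather than producing
divide-by-small artifacts.  For each molecule the first five valid frames
are pooled into the condition histogram (0.02-wide half-open bins over
[−0.1, 1.1]; values clipped to [−0.2, 1.2] for binning only); a warning is
logged when fewer than 2000 molecules contribute, the scale of the
published histograms.  Pooled values are classified as donor-only
(E ≤ 0.2), low FRET (0.2 < E < boundary) or high FRET (E ≥ boundary), with
the boundary in {0.6, 0.65, 0.7} and 0.65 — the middle of that customary
set — as default.  Values exactly at a threshold go to the side that cannot
inflate f_unwound (donor-only and high, respectively).

f_unwound = n_low/(n_low + n_high).  The donor-only population is excluded
from the denominator because those molecules carry no unwinding
information and the acquisition already tries to exclude them; the
alternative convention (donor-only in the denominator) is available behind
`include_donor_only=True`.  The SD is a seeded nonparametric bootstrap
(default 1000 resamples) over *molecules*, not frames — frames within a
molecule are strongly correlated under slow exchange — and matches the
binomial closed form sqrt(f(1−f)/n_molecules) on simulated data.  Whether
the originally reported SDs are replicate-based or bootstrap-based is not
stated; bootstrap was chosen as the convention here.  The mean E of the
low-FRET population is reported alongside f_unwound (it shifts with gRNA
extensions).

### Noise regimes and estimator bias

Threshold classification of per-frame E values is unbiased only while the
peak widths are small relative to the margin between a state and the
boundary.  With the high-FRET state at 0.75 and the boundary at 0.65, a
per-frame E SD of 0.08 puts the boundary 1.25σ from the peak, so ≈ 10% of
rewound frames classify as low-FRET while ≈ 10% of unwound frames fall
into the donor-only bin; the net effect inflates f_unwound by up to ≈ +0.1
at low occupancy (the two leakages cancel at high occupancy).  At the
package's default broadening (E SD ≈ 0.04, boundary 2.5σ from either peak)
the recovery error stays below 0.015 across the whole occupancy range, and
the boundary choice within {0.6, 0.65, 0.7} moves f_unwound by < 0.02.
This is a property of the published classification rule itself, not of the
implementation; analyses of broad histograms should treat absolute
f_unwound values near 0 with care.

## Promiscuity and specificity

    promiscuity = Σ_{n_PD=1}^{3} n_PD · f_unwound(n_PD)
    S = f_unwound(0) / promiscuity

The summation range is n_PD ∈ {1, 2, 3} (targets with one, two and three
PAM-distal mismatches); n_PD = 4 data, where present, is reported but never
enters S.  Promiscuity SD is quadrature over the independent conditions;
S uncertainty is first-order (delta-method) propagation of the ratio,
validated against Monte-Carlo resampling in the tests.  Zero promiscuity
makes S undefined (a perfectly specific enzyme) and is reported as an
error rather than infinity.  Truncated gRNAs (X18, gX18, X17) cannot pair
all 20 protospacer nucleotides, so promiscuity and S are not defined for
them; comparison tables keep their on-target activity and leave S empty.

## The demonstration panel

`make_demo_panel` builds a 5-variant × n_PD 0–3 panel (canonical gRNA)
whose occupancy profiles are synthetic stand-ins chosen once so that the
implied S values equal the reported per-variant specificities (0.23 WT,
0.50 Hypa, 0.53 Sniper, 0.66 HF1, 0.71 eCas9) while keeping the
qualitative shape of the measured profiles: f_unwound decreasing with
n_PD, WT promiscuity far above the engineered variants, HypaCas9's reduced
on-target activity, SniperCas9 more promiscuous than the other engineered
variants.  Each condition simulates 3000 molecules — comfortably above the
">2000 molecules per histogram" scale of the source assays — which puts
the sampling SE of a recovered S near 0.015 and makes the ranking
reproducible under reseeding.  The panel demonstrates that the pipeline
recovers designed specificities; it does not re-measure the biology.

## Problem sizes and numerical choices

Default problem sizes were picked so every stage is exercised at
meaningful statistics: 3000 molecules × 6–8 frames for trace-level
estimates, 200-molecule movies (300×600 px, 6 frames) for image-level
round trips, 1000 bootstrap resamples.  All randomness flows from one
top-level seed through numpy `SeedSequence` children (placement, labels,
state trajectories, signal noise, camera noise), so identical seeds give
bit-identical traces, movies and tables; every pipeline run writes its
config, versions and per-stage molecule counts to a JSON manifest.
Degenerate inputs are rejected eagerly with the offending field named
(inconsistent rate/occupancy pairs, odd movie widths, overcrowded fields,
non-positive bin widths, conditions with no FRET-active molecules).

## What the synthetic data does not show

The generator emulates the statistical structure the analysis relies on —
two FRET populations with state-dependent means, roughly constant total
emission, a donor-only peak, additive camera noise, single-step bleaching —
but not diffusing molecules, stage drift, spectral crosstalk, non-Gaussian
EMCCD gain statistics, dye blinking, or sequence-dependent kinetics.
Passing tests therefore certify the correctness of the analysis chain and
its estimators on data obeying the stated model, not the biological
conclusions drawn from real recordings; with no public deposition of the
original movies, the printed per-variant values enter only as design
targets for the synthetic panel.
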
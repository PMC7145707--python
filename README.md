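# smfret-unwind

Single-molecule FRET analysis of Cas9-induced DNA unwinding.

CRISPR-Cas9 must unwind its DNA target before it can cleave it, and this
unwinding step acts as a specificity checkpoint: mismatches between the
guide RNA (gRNA) and the PAM-distal end of the protospacer shift the
Cas9-RNA-DNA complex from an *unwound* (R-loop open) conformation back to a
*rewound* (duplex reformed) one.  In smFRET assays the two conformations are
read out per molecule through the FRET efficiency of a donor/acceptor pair
on the target DNA: the rewound state sits at E ≈ 0.75 and the unwound state
at E ≈ 0.3.  This package implements the full analysis chain used to turn
such recordings into quantitative specificity comparisons across Cas9
variants (WT, eCas9, Cas9-HF1, HypaCas9, SniperCas9) and gRNA designs
(canonical X20, 5'-extended gX20/ggX20, 5'-truncated X18/gX18/X17):

1. **synthetic data** — ground-truth-labeled two-state kinetic simulations
   of immobilized molecules, as intensity traces or as rendered dual-channel
   16-bit movie stacks (donor on the left camera half, acceptor on the
   right), with donor-only molecules, photobleaching, background and noise;
2. **trace extraction** — spot detection on the time-averaged acceptor
   channel (excluding molecules with a missing/inactive acceptor),
   channel registration, and circular-aperture photometry with
   annulus-median local background, yielding background-corrected
   I_D(t), I_A(t);
3. **FRET analysis** — per-frame E = I_A/(I_D + I_A), condition-level E
   histograms pooling the first five data points of each molecule
   (>2000 molecules per histogram at full scale), threshold classification
   into donor-only (E ≤ 0.2), low-FRET/unwound (0.2 < E < 0.65) and
   high-FRET/rewound (E ≥ 0.65) populations, and the unwound fraction

       f_unwound = n_low / (n_low + n_high)

   with a molecule-level bootstrap SD;
4. **specificity scoring** — unwinding promiscuity and the specificity S

       promiscuity = Σ_{n_PD=1..3} n_PD · f_unwound(n_PD)
       S = f_unwound(0) / promiscuity

   where n_PD is the number of PAM-distal mismatches; truncated gRNAs get
   on-target activity but no S (it is undefined for them).

It is aimed at single-molecule biophysicists who want a tested, scriptable
re-implementation of this analysis that can be validated end to end on
synthetic data with known ground truth.

## Worked example

The built-in demonstration panel simulates the five Cas9 variants with
canonical gRNA at n_PD = 0–3, using synthetic occupancy profiles whose
implied specificities equal the reported per-variant values, then runs the
whole pipeline (simulate → analyze → score):

```bash
smfret-unwind demo --seed 0 --out results/demo --run
```

prints (3000 molecules per condition; ~10 s):

```
     label grna  on_target  on_target_sd  promiscuity  promiscuity_sd        S     sd_S
     eCas9  X20   0.856930      0.006496     1.197035        0.026701 0.715877 0.016865
  Cas9-HF1  X20   0.856021      0.006821     1.297843        0.026161 0.659572 0.014296
SniperCas9  X20   0.905152      0.005668     1.704838        0.028395 0.530931 0.009447
  HypaCas9  X20   0.540792      0.009793     1.081924        0.024590 0.499843 0.014525
    WTCas9  X20   0.923567      0.005060     3.937334        0.032433 0.234567 0.002321
```

Reading the table: `on_target` is f_unwound for cognate DNA, `promiscuity`
aggregates mismatched-target unwinding weighted by n_PD, and `S` is their
ratio — the recovered values sit within sampling error of the
simulation-design targets 0.71 / 0.66 / 0.53 / 0.50 / 0.23 and reproduce
the ordering WT < Hypa < Sniper < HF1 < eCas9 (WT Cas9 is the least
specific because it keeps unwinding mismatched targets; HypaCas9 loses
specificity through weak on-target unwinding instead).  The output
directory also contains per-condition traces, E histograms, an estimates
table, an on-target-vs-promiscuity scatter plot, and a machine-readable run
manifest.

Each stage is also available separately (`smfret-unwind simulate|extract|
analyze|score|run`), e.g. movie-level processing:

```bash
smfret-unwind extract --movie movie.tif --offset 1.0,-1.5 --out results/extract
smfret-unwind analyze --traces results/extract/traces.tsv --boundary 0.65 --out results/ana
```

or from Python:

```python
from smfret_unwind import (KineticParams, PhotophysicsParams, ConditionSpec,
                           simulate_trace_set, fret_from_traces, estimate_f_unwound)

cond = ConditionSpec(label="WT", n_pd=0, kinetics=KineticParams(p_unwound=0.6),
                     photophysics=PhotophysicsParams())
traces, truth = simulate_trace_set(cond, n_molecules=3000, n_frames=8, seed=1)
est = estimate_f_unwound(fret_from_traces(traces, configured_total=500.0), seed=2)
print(est.f_unwound, est.sd)   # ~0.60 ± 0.009
```

## Layout

```
src/smfret_unwind/
  params.py        kinetic / photophysics / movie / condition parameters
  simulate.py      state trajectories, trace sets, movie rendering
  extract.py       channel splitting, spot detection, photometry
  fret.py          E series, histograms, classification, f_unwound
  specificity.py   promiscuity, S, cross-condition comparison
  pipeline.py      orchestration, config, demo panel
  cli.py           command-line interface
docs/methods.md    model, assumptions, parameter choices, limitations
```
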
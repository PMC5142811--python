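# wormscreen

Analysis tools for pan-neuronal calcium-imaging screens and behavioral
assays in *C. elegans* thermal-stimulation experiments.

Pan-neuronal recordings image the nuclei of most head neurons at once while
a timed thermal stimulus (e.g. 5 cycles of a 20 s noxious heat pulse with a
30 s interstimulus interval, after a 50 s baseline) is applied to a
paralyzed worm. Turning such a recording into per-neuron physiology, and a
plate of freely crawling worms into transition-rate statistics, requires a
chain of well-defined steps. This package implements that chain as a
tested, scriptable library:

- **Preprocessing** — rigid motion correction by upsampled cross-correlation
  (single-step DFT subpixel registration, estimated on the
  activity-independent reference channel and applied to both channels), and
  optional Richardson–Lucy 3D deconvolution with mirrored boundaries.
- **Nucleus detection and tracking** — a gradient vector field (GVF) is
  diffused from the smoothed intensity gradient
  (`v ← v + dt·[μ∇²v − (v − ∇f)|∇f|²]`); every voxel is advected along the
  field to a convergence point, convergence points are clustered into
  nucleus centers, and each neuron is followed frame-to-frame by re-running
  the flow inside a small crop around its last position.
- **Ratiometric traces** — the G/R ratio (calcium indicator over
  co-expressed reference) measured in a spherical mask at each tracked
  center, normalized to the time-series minimum, resampled by linear
  interpolation, and averaged with standard errors across worms.
- **Stimulus screening** — Pearson correlation of each trace with the
  stimulus boxcar classifies neurons as positively correlated, negatively
  correlated, or uncorrelated; per-cycle response amplitudes quantify
  adaptation as (A₁ − A_last)/A₁.
- **Ethogram statistics** — behavior fractions per stimulation phase
  (P, H1–H5, L1–L5), transition events with their pre-transition bout
  durations, harmonic-mean transition rates `k = n / Σᵢ dᵢ` with
  leave-one-out jackknife SDs, bias-corrected (BC) percentile bootstrap
  confidence intervals at the 83.4% level (chosen so non-overlapping error
  bars correspond to p < 0.05), Mann–Whitney comparisons against a control
  strain, post-stimulus reversal durations, and behavior-network graphs
  (GraphML; node = behavior fraction, edge width ∝ transition rate).
- **Synthetic generators** — ground-truthed two-channel recordings of
  drifting, stimulus-responsive nuclei, and 4-state continuous-time Markov
  chain ethograms with phase-dependent rates, so every stage is testable
  without microscope data.

## Worked example

Simulate plate assays for a responsive ("wild-type") and a blunted
("mutant") strain, then compute the forward→reversal transition rate during
the first heating phase:

```python
import numpy as np
from wormscreen import (
    StimulusProtocol, default_ctmc, simulate_ethograms,
    phase_windows, extract_transitions, transition_rate,
    bootstrap_ci, harmonic_mean_rate,
)

protocol = StimulusProtocol()          # 50 s pre, then 5 x (20 s heat + 30 s ISI)
windows = phase_windows(protocol)

wt, _ = simulate_ethograms(default_ctmc(heat_fr_boost=10), protocol,
                           n_worms=40, fps=20, seed=1)
mut, _ = simulate_ethograms(default_ctmc(heat_fr_boost=2), protocol,
                            n_worms=40, fps=20, seed=2)

for name, ethos in (("wild-type", wt), ("mutant", mut)):
    durations = [ev.pre_duration
                 for e in ethos
                 for ev in extract_transitions(e, min_bout=2, windows=windows)
                 if (ev.from_behavior, ev.to_behavior, ev.phase)
                 == ("forward", "reversal", "H1")]
    rate, jack_sd = transition_rate(durations)
    lo, hi = bootstrap_ci(np.asarray(durations), harmonic_mean_rate,
                          level=0.834, B=1000, seed=0)
    print(f"{name}: F->R rate in H1 = {rate:.3f} /s "
          f"(jackknife SD {jack_sd:.3f}, 83.4% CI [{lo:.3f}, {hi:.3f}], "
          f"n={len(durations)})")
```

which prints:

```
wild-type: F->R rate in H1 = 0.098 /s (jackknife SD 0.014, 83.4% CI [0.080, 0.119], n=94)
mutant: F->R rate in H1 = 0.049 /s (jackknife SD 0.010, 83.4% CI [0.038, 0.063], n=23)
```

The wild-type's forward→reversal rate during heating is about twice the
mutant's, with clearly separated 83.4% intervals — the rate-based readout
resolves a difference of this size with 40 worms per plate.  (The
harmonic-mean rate is lower than the generator's instantaneous heat-phase
rate because forward bouts that began before the heat pulse carry their full
pre-transition duration; see `docs/methods.md`.)

The same analyses are available from the shell:

```sh
wormscreen simulate ethogram --n 40 --fps 20 --seed 1 --out etho.csv
wormscreen etho stats etho.csv proto.json --boot 1000 --level 0.834 --seed 7 --out stats/
wormscreen run imaging config.json      # register -> detect -> track -> extract -> screen
```

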
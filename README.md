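# optorecruit

Quantification pipeline for optogenetic membrane-recruitment
experiments in endothelial cells.

Light-induced heterodimerization tools (iLID-type bait/prey pairs)
recruit a cytosolic protein — for example a RhoGEF catalytic domain —
to the plasma membrane while blue light is on, and release it in the
dark. Studies built on these tools all quantify the same families of
read-outs: how fast and how strongly the prey is recruited, how cell
shape and area respond, how straight the cell–cell junctions are, how
much neighboring membranes overlap, and how the monolayer's electrical
resistance (a proxy for vascular barrier strength) reacts to the
stimulus. `optorecruit` implements these measurements as a tested
library, driven by a synthetic scene generator that provides ground
truth for every stage, so the whole pipeline is verifiable without any
microscopy downloads.

## Core quantities

* **Recruitment kinetics** — normalized membrane/cytosol intensity
  ratio R(t); mono-exponential fits R = R₀ + A(1 − e^−t/τ) (ON) and
  R = R₀ + A·e^−t/τ (OFF) with half-times t½ = ln 2·τ; plateau
  recruitment efficiency; cytosol-depletion and sensor-relocation
  percentages.
* **Morphometry** — nucleus-seeded watershed segmentation, overlap
  tracking, normalized area traces, form factor 4πA/P² (1 = circle),
  contraction/extension change maps, activation-ROI coverage, mosaic
  membrane-overlap series.
* **Junctions** — linearity index = junction perimeter / corner-polygon
  perimeter (1 = straight junction), bootstrap group summaries,
  temporal color-coded projections.
* **Traces & optics** — resistance-trace normalization, signed response
  amplitudes, area/resistance correlation, permeability-well averaging;
  Airy first-ring area πr², r = 1.22λ/(2·NA), and power density.

## Worked example

```python
from optorecruit.imaging import RoiSet
from optorecruit.kinetics import fit_monoexp, ratio_trace, recruitment_efficiency
from optorecruit.scenes import SceneConfig, simulate_recruitment_stack

config = SceneConfig()            # tau_on=8 s, tau_off=20 s, 2.5 s frames
stack, truth = simulate_recruitment_stack(config)
rois = RoiSet(masks={"membrane": truth.membrane_mask,
                     "cytosol": truth.cytosol_mask})
trace = ratio_trace(stack, rois, stim_windows=list(config.stim_windows))

on = fit_monoexp(trace, "ON", config.stim_windows[0])
off = fit_monoexp(trace, "OFF", (config.stim_windows[0][1], 240.0))
print(f"t1/2 ON  = {on.t_half:.3f} s")
print(f"t1/2 OFF = {off.t_half:.3f} s")
print(f"efficiency = {recruitment_efficiency(trace):.3f}")
```

prints

```
t1/2 ON  = 5.545 s
t1/2 OFF = 13.863 s
efficiency = 2.148
```

i.e. the fits recover the generating half-times (ln 2·8 = 5.545 s,
ln 2·20 = 13.863 s) exactly on the noiseless scene, and the plateau
ratio of ≈ 2 reflects the configured membrane-bound pool fraction of
0.15 through the disk-phantom geometry.

The numbered scripts under `analysis/` run the same stages as narrative
analyses (scene generation, kinetics recovery over 50 seeds, junction
linearity populations, morphometry, traces/optics) and write tidy CSV
tables under `results/`. A thin CLI mirrors them:
`optorecruit run --seed 0 --out results/run0`.

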
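# swarmotility

Analysis toolkit for the chemosensory physiology of surface-swarming
*E. coli*.  Cells lifted from a swarm and returned to liquid swim
differently from liquid-grown cells: they tumble far less (median
tumble bias ~0.04 vs ~0.12), swim faster (~25 vs ~21 μm/s), their
flagellar motors reverse rarely (~9 vs ~38 reversals/min) while
spinning faster, and the change traces to post-transcriptionally
elevated, more stable CheZ — the phosphatase that drains CheY~P, the
signal that makes motors turn clockwise and cells tumble.  This
package implements the complete measurement chain behind those
statements, plus a synthetic-data generator that emulates every input,
so the whole pipeline is testable end to end without microscope data.

It is aimed at quantitative microbiologists and biophysicists who work
with single-cell tracking, tethered-bead motor assays, western-blot
densitometry, or single-cell fluorescence, and want seeded, inspectable
reference implementations of the associated estimators.

## What is inside

| module | contents |
|---|---|
| `synthetic` / `presets` | run-and-tumble swimmers with Brownian non-motile cells; CW/CCW motor telegraph traces rendered as orbiting bead coordinates; exponential protein-decay courses with lognormal noise; two-channel fluorescence scenes — each with ground truth and condition presets (`liquid`, `swarm`, `hard`) |
| `tracking` | temporal-mean background subtraction, matched-filter spot detection with Benjamini–Hochberg FDR control, radial-symmetry subpixel localization, Hungarian motion-model linking with gap closing, minimum-duration filtering |
| `motility` | MSD diffusion coefficient (`MSD = 4Dτ`), motile classification (10 μm²/s threshold), run/tumble segmentation, tumble bias, tumble-excluded swimming speed, duration-weighted population summaries |
| `motor` | signed rotation frequency from bead orbits (CW positive), reversal counting with debounce, CW bias, torque `τ = 2πf·(8πηa³ + 6πηa·r_e²)` |
| `blotquant` | loading-control normalization, condition fold-changes with t-tests, chloramphenicol-chase first-order decay-rate fits |
| `fluorquant` | segmentation, 3-SD size filter, background/autofluorescence-corrected per-cell totals, CheZ/CheY expression-ratio statistics |
| `stats` | trajectory-weighted one-way ANOVA F with a 10,000-permutation null, add-one p-values, KS comparison against the analytic F(K−1, n−K) |
| `signaling` | Goldbeter–Koshland futile cycle in closed form; zero-order ultrasensitivity mapping CheZ fold-change to tumble bias through a Hill motor response |
| `trajio` / `pipeline` / `cli` | trajectory CSV and 16-bit TIFF I/O, JSON run reports, end-to-end pipeline, `swarmotility` command |

The central statistic, the **tumble bias**, is the fraction of frames a
cell spends tumbling; swimming speed is averaged over run frames only.
Conditions are compared with the duration-weighted one-way ANOVA

    F = [Σ_g W_g(ȳ_g − ȳ)²/(K−1)] / [Σ_i w_i(y_i − ȳ_g(i))²/(n−K)],

whose null distribution is obtained by permuting trajectories between
groups, because trajectory weighting and non-normal per-cell statistics
void the textbook F assumptions.  See `docs/methods.md` for models,
estimator calibration, and numerical choices.

## Worked example

Simulate 100 cells per condition for 100 s at 10 fps, run the motility
pipeline and the trajectory-weighted permutation ANOVA:

```sh
$ swarmotility demo --n-cells 100 --seed 1 --out report.json
liquid: TB median 0.122, speed median 20.9 um/s
swarm: TB median 0.041, speed median 25.0 um/s
ANOVA p (tumble bias): 5.00e-04
```

The liquid population recovers the generative tumble bias 0.12 and run
speed 21 μm/s; the swarm population recovers 0.04 and 25 μm/s; the
permutation p-value (2,000 permutations here) says the two conditions
are cleanly distinguishable — the add-one estimator bottoms out at
1/(n_perm+1), so 5.0e-4 is the smallest value this run can report.

The futile-cycle model shows why a modest CheZ increase suffices:

```sh
$ swarmotility signal --folds 1.0,1.3,1.5 --out curve.csv
 fold  V_Z       yp  tumble_bias
  1.0  1.0 0.261854 1.200000e-01
  1.3  1.3 0.028959 3.731582e-11
  1.5  1.5 0.018112 3.418159e-13
```

With both enzymes near saturation (Michaelis constants 1% of total
CheY), raising the phosphatase rate 1.3× drops the CheY~P fraction from
0.26 to 0.03 and the predicted tumble bias collapses — zero-order
ultrasensitivity.  Re-run with `--michaelis 10` to see the first-order
regime, where the same fold barely moves the output.

Python API equivalent:

```python
from swarmotility import make_preset, synthetic, motility

tset = synthetic.simulate_population(make_preset("swarm"), 100, 100.0, 0.1, seed=1)
pop = motility.population_summary(motility.analyze_population(tset))
print(pop["tumble_bias_weighted_median"])   # ~0.04
```

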
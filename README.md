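# chromodyn

Quantifying how strongly a nuclear protein engages chromatin in live
cells, from two complementary live-imaging readouts:

- **fast single-molecule tracking (SMT):** sparse photoactivated
  molecules are detected frame by frame, linked into trajectories, and
  the distribution of diffusion coefficients is inferred per cell; the
  *chromatin-bound fraction* is the share of molecules with
  D < 0.1 µm²/s.
- **3D FRAP of chromocenters:** a DNA-dense focus is partially bleached
  and the corrected fluorescence recovery is summarized by bleach depth
  I_min, maximal recovery I_max and time to half-recovery t½.

The motivating application is MeCP2, the methyl-CpG–binding protein
mutated in Rett syndrome: a partial-loss-of-function mutation in its
methyl-CpG-binding domain (G118E) both lowers protein levels and,
independently, weakens chromatin binding — visible as a drop in bound
fraction (≈64% → ≈39%), a faster FRAP half-recovery (≈26 s → ≈13 s)
and a shallower bleach depth. The package also ships the statistics used
to *uncouple* those two effects: per-cell detection counts as an
expression proxy, Pearson correlation with a seeded random-pairing null,
and high/low-expression stratification of FRAP curves.

Every stage is testable without any microscopy data: a synthetic-data
module generates trajectories, rendered movies and FRAP series with
known ground truth under the acquisition geometry of the real
experiments (0.16 µm pixels, 7.48 ms frames, 0.7 µm focal depth,
~1 localization/frame).

## The model in brief

A molecule is bound (D_b ≈ 0.02 µm²/s) or free (D_f ≈ 2–12 µm²/s) and
performs Brownian motion in 3D; it is observed with per-axis Gaussian
localization error σ while its axial position stays inside the
±Δz/2 detection slab, until photobleaching. Jumps of an observed
trajectory are scored under regular Brownian motion with localization
error (RBME): per axis the jump vector is zero-mean multivariate normal
with tridiagonal covariance

    C_ii = 2 D Δt + 2 σ²,   C_i,i±1 = −σ².

A state array — a fixed log-spaced grid of 100 coefficients from 10⁻²
to 10² µm²/s — carries an occupation vector estimated per cell by
expectation–maximization; occupations of observed jumps are converted to
per-molecule occupations by dividing by the expected number of observed
jumps per molecule at each coefficient (slow molecules stay in the slab
longer, so raw jump counts over-represent them). The bound fraction is
the occupation strictly below 0.1 µm²/s.

FRAP series are corrected as: background-subtract chromocenter and
nucleus, normalize each to its pre-bleach mean, divide frame by frame
(acquisition photobleaching cancels exactly), average over cells, then
read I_min (first post-bleach value), I_max (late-time recovery) and t½
(first crossing of I_min + (I_max − I_min)/2).

## Worked example

```python
import chromodyn as cd

cfg = cd.ImagingConfig()                      # 0.16 µm px, 7.48 ms frames
traj, truth = cd.simulate_trajectories(
    cd.PRESETS["WT"].two_state, cfg, n_cells=5, traj_per_cell=250, seed=1)
spec = cd.state_array_infer(traj, cfg=cfg)
print(f"simulated bound fraction (ground truth): "
      f"{truth.per_trajectory['bound'].mean():.3f}")
print(f"recovered bound fraction:               "
      f"{spec.aggregate_bound_fraction():.3f}")

cells, _ = cd.simulate_frap(cd.PRESETS["WT"].frap, n_cells=23, seed=1)
curves, kept, n_excluded = cd.correct_cells(cells)
mean, sd, summ = cd.average_and_summarize(curves, cells[0].times, n_pre=5)
print(f"FRAP: I_min={summ.i_min:.2f}  I_max={summ.i_max:.2f}  "
      f"t_half={summ.t_half:.1f} s  ({n_excluded} cells excluded)")
```

prints

```
simulated bound fraction (ground truth): 0.634
recovered bound fraction:               0.648
FRAP: I_min=0.44  I_max=0.91  t_half=25.6 s  (0 cells excluded)
```

The wild-type preset puts 64% of molecules in the bound state; the full
detection-free inference recovers that fraction to within a couple of
points at five cells, and the FRAP pipeline recovers the preset's 26 s
half-time and 0.92 plateau despite the injected acquisition-bleaching
decay (the correction cancels it).

A command-line interface mirrors the library stages for file-to-file
use: `chromodyn simulate | detect | track | infer | frap | couple`
(see `chromodyn --help`).

## Layout

| module | what it does |
| --- | --- |
| `chromodyn.config` | shared imaging configuration (pixel size, Δt, Δz, σ) |
| `chromodyn.simulate` | two-state trajectory / movie / FRAP generators with ground truth |
| `chromodyn.detect` | LLR spot detection, integrated-Gaussian subpixel fits, QC rule |
| `chromodyn.link` | frame-to-frame bipartite linking, jump-length statistics |
| `chromodyn.spectrum` | RBME likelihood, state-array inference, bound fraction |
| `chromodyn.frap` | FRAP correction, averaging, I_min/I_max/t½, group comparison |
| `chromodyn.coupling` | expression-proxy correlations, permutation null, stratification |

See `docs/methods.md` for the methods note (model assumptions, parameter
choices, numerical details, limitations).
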
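# cochreg

Landmark-based affine registration of a parametric cochlear model to
landmarks picked in conventional CT of the human inner ear.

## The problem

Cochlear implant planning needs patient-specific cochlear anatomy, but the
cochlea (~9 × 7 × 4 mm) is barely resolved by the 0.3 mm voxels of routine
clinical CT. Instead of segmenting the cochlea outright, a parametric model
of the cochlear spiral can be fitted to a handful of corresponding
landmarks placed on the lateral wall in the scan: the registered model then
carries the anatomical measurements. `cochreg` implements that pipeline for
researchers working with such data:

- a **parametric lateral-wall model** centered at the origin, defined by
  four quadrant extents `A_a, A_b, B_a, B_b` (mm) that fix the basal-turn
  footprint, a number of turns (computed from the extents or fixed
  explicitly) and an apical height;
- **angular landmark placement** (one landmark every 45°/90°/180° along the
  unwound spiral plus a terminal landmark at the apex, or a minimal
  5-landmark scheme), with strict index correspondence between model and
  patient sides;
- **affine registration**: the transform `f_T = f_F ∘ f_{R,t} ∘ f_C ∘ f_S`
  (shear, anisotropic scale, rotation + translation, axis reflection) with
  continuous parameter vector
  `p* = (α, β, γ, t_x, t_y, t_z, c_x, c_y, c_z, s_xy, s_xz, s_yz)`,
  fitted by quasi-Newton (BFGS) minimization of the landmark SSD
  `Σᵢ ‖f_T(l_M,i; p*) − l_C,i‖²` starting from the identity, stopping when
  the SSD change drops below 1e-6 mm² (at most 100 iterations); reflection
  is handled by an optional exhaustive search over the 8 axis-sign flags;
- **quadrant-parameter estimation** from two perpendicular basal-turn
  chords (`A_a = |P1M|`, `A_b = |MP2|`, `B_a = |Q1M|`, `B_b = |MQ2|`, with
  M the least-squares closest point to the two chord lines);
- **worst-landmark pruning**: register → rank landmarks by residual error →
  delete the worst batch from both sides → re-register, with protected
  labels (typically the apex) and per-step MAE reporting;
- a **phantom generator** producing ground-truth test cases: the model
  posed by a known random affine transform, with coordinates quantized to
  the CT voxel grid, plus optional NIfTI voxel masks.

## Worked example

```python
from cochreg import PhantomSpec, make_phantom, register

phantom = make_phantom(PhantomSpec(seed=42, noise="quantize"))
result = register(phantom.model_landmarks, phantom.target_landmarks)
print(result.iterations, result.mae)
```

Running `python examples/register_phantom.py` (the same computation with
diagnostics) prints:

```
landmark pairs : 12
iterations     : 18
final SSD      : 0.115301 mm^2
MAE            : 0.0907 mm  (CT voxel edge: 0.3 mm)
matrix error   : 5.32e-02 (max abs entry difference vs the true pose)
```

The 12 model landmarks (mean cochlea, 90° spacing) were posed by a hidden
random affine transform and snapped to a 0.3 mm voxel grid; registration
recovers the pose in 18 quasi-Newton iterations with a mean per-landmark
error of 0.09 mm — below the scanner resolution, which is the practically
relevant bar. The other scripts in `examples/` demonstrate model building
and landmark counting, chord-based parameter estimation, and iterative
pruning (where the MAE falls step by step as the worst landmarks are
deleted, e.g. from 0.143 mm at 20 landmarks to 0.049 mm at 9 in
`examples/prune_landmarks.py`).

A thin CLI wraps the same functions for shell use
(`cochreg model | fit | prune | phantom | params-estimate`); every
subcommand writes its resolved configuration beside its outputs. See
`cochreg --help`.

## Layout

- `src/cochreg/model.py` — parametric centerline, turns law
- `src/cochreg/landmarks.py` — placement schemes, chord-based parameter
  estimation, paired deletion
- `src/cochreg/registration.py` — transform composition, SSD objective and
  gradient, quasi-Newton fitting, closed-form affine reference
- `src/cochreg/refinement.py` — worst-landmark pruning workflow
- `src/cochreg/synthetic.py` — phantom generator, voxel-mask rasterization
- `src/cochreg/io.py`, `src/cochreg/cli.py` — file formats and the CLI

`docs/methods.md` documents the model, the numerical choices and the known
limitations.
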
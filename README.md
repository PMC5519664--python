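# flowpost

Postprocessing of 4D-flow (time-resolved phase-contrast MRI) velocity
volumes: vessel-lumen segmentation, surface extraction, wall shear stress
(WSS), viscous flow energy loss (EL) under eddy-viscosity turbulence
closures, cross-sectional flow rates, and velocity-field comparison
statistics — validated against analytic flow phantoms with closed-form
ground truth.

## What it does

| Module | Purpose |
| --- | --- |
| `flowpost.io_grids` | Grid/field/mask/mesh types and I/O (NIfTI-1, NRRD, legacy-VTK volumes; STL/PLY/VTP meshes; JSON/CSV reports). Spacing is stored in mm, all physics is computed in SI. |
| `flowpost.segmentation` | Speed volume → threshold → seeded 3-D region growing → speed-based boundary refinement (plus a scriptable manual-edit hook) → marching cubes (iso 0.5) → Laplacian smoothing. |
| `flowpost.hemodynamics` | WSS per surface face (`mu * v_tangential / depth`, velocity sampled a half voxel inside along the normal, wall velocity zero); strain-rate tensor on masked grids; EL = ∫(μ+μt)·Σ½(∂ui/∂xj+∂uj/∂xi)² dV with laminar / Smagorinsky-LES / RNG k–ε closures (μt = Cμρk²/ε from supplied k, ε fields); boundary-layer (outermost voxel shell) EL decomposition; plane flow-rate integration; cubic-spline inlet waveforms. |
| `flowpost.comparison` | Linear resampling of one field onto another's grid, three-region partition (ascending / arch / descending by two cut planes), per-region per-component Pearson r with p-values and mean ± SD absolute error. |
| `flowpost.synthetic` | Analytic phantoms (Poiseuille, Womersley, rigid rotation, branching tube) voxelized at PC-MRI-like resolutions with exact flow/WSS/EL ground truth, and a PC-MRI degradation model (partial-volume box averaging, Gaussian noise, venc phase wrapping) that reproduces flow underestimation in small vessels. |
| `flowpost.cli` | `flowpost` command with `phantom`, `degrade`, `segment`, `wss`, `el`, `flowrate`, `compare`, and `run` (declarative YAML pipeline with a reproducibility manifest). |

Default fluid constants: μ = 0.004 Pa·s, ρ = 1060 kg/m³; closure constants
Cμ = 0.0845, Cs = 0.1; all configurable.

## CLI quick start

```sh
# generate a Poiseuille phantom (velocity + lumen mask + ground truth)
cat > spec.yaml <<EOF
kind: poiseuille
radius: 10.0        # mm
length: 100.0       # mm
flow_rate_lpm: 5.0
spacing: [1.0, 1.0, 1.0]
EOF
flowpost phantom --spec spec.yaml --outdir phantom/

# segment and extract the smoothed surface
flowpost segment --velocity phantom/velocity.nii --threshold 0.02 \
    --seed-voxel 12 12 50 --mask-out mask.nii --mesh-out surface.stl

# wall shear stress (JSON report + VTP mesh with per-face WSS)
flowpost wss --velocity phantom/velocity.nii --mesh surface.stl \
    --out wss.json --mesh-out wss.vtp

# energy loss and flow rate
flowpost el --velocity phantom/velocity.nii --mask mask.nii \
    --closure laminar --out el.json
flowpost flowrate --velocity phantom/velocity.nii --mask mask.nii \
    --origin 0 0 50 --normal 0 0 1 --out q.json
```

A whole pipeline (phantom → degrade → segment → wss/el/flowrate → compare)
runs from one config:

```sh
flowpost run --config pipeline.yaml
```

Every run writes a `manifest.json` recording the package version, the full
config, and the seed, so any result file traces back to the exact parameters
that produced it. See `tests/test_cli.py::pipeline_config` for a complete
config example.

## Conventions

- Voxel indices are 0-based; world position = origin + index × spacing
  (mm); values live at voxel centers. Axis labels map grid axes to
  anatomical directions (AP, RL, SI); velocity components are ordered
  (AP, RL, SI).
- Time-resolved fields are supported in storage; analysis operations act on
  one selected frame (peak systole in the intended workflow).
- The world coordinate frame is right-handed with no claim about
  scanner-frame handedness; files written by this package document their own
  convention.
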
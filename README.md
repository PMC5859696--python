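# ventriflow

Left-ventricular (LV) flow-component and kinetic-energy analysis for 4D flow
cardiovascular MR (CMR) velocity data.

4D flow CMR measures three-directional blood velocity in a 3D volume over the
cardiac cycle. A functional way to read such data is to partition the LV
end-diastolic blood volume by the fate and history of each parcel of blood:
emit one pathline from the center of every end-diastolic (ED) mask voxel,
integrate it forward through systole and backward through diastole to the two
neighbouring end-systoles (ES), and test both endpoints against the segmented
end-systolic volume (ESV):

| origin in ESV? | destination in ESV? | component |
|---|---|---|
| no  | no  | **Direct Flow** (enters this diastole, ejected this systole) |
| no  | yes | **Retained Inflow** (enters, not ejected) |
| yes | no  | **Delayed Ejection Flow** (already inside, ejected) |
| yes | yes | **Residual Volume** (stays at least two cycles) |

The two inflow components are further split by diastolic filling phase:
pathlines whose first mitral-plane crossing precedes mid-diastasis belong to
the early filling wave (E), the rest to the atrial wave (A). Mid-diastasis is
found from the data as the diastolic frame interval in which the fewest
inflow pathlines cross the mitral valve plane.

Each pathline represents one voxel volume V of blood, so a component's
kinetic energy at frame *t* is

    KE(t) = Σ_pathlines ½ ρ V |v(t)|²

with blood density ρ (default 1060 kg/m³) and the interpolated field speed at
the pathline position. KE and KE/ml evaluated at ED are the *pre-systolic*
energetic summaries used for group comparison; they index how much motion the
inflowing blood retains at the moment systole begins, which is blunted when
early diastolic relaxation is dyssynchronous (e.g. left bundle branch block).

The package contains:

- `phantom` — synthetic slab and rotation phantoms with closed-form ground
  truth for every downstream stage (component volumes, E/A split,
  mid-diastasis frame, KE curves), plus artifact injection;
- `flow_io` — NIfTI + JSON-sidecar dataset layout, shared constants, result
  files;
- `preprocess` — background phase-offset correction (degree-4 3D polynomial
  fitted to static tissue) and temporal phase unwrapping at the VENC
  threshold;
- `pathline_engine` — trilinear/periodic-linear interpolation and fixed-step
  RK4 pathline integration over one cardiac cycle;
- `flow_components` — the four-way classification, E/A split and the 15 %
  inflow–outflow quality-control rule;
- `energetics` — KE curves and pre-systolic summaries;
- `group_stats` — Kolmogorov–Smirnov (Lilliefors) normality routing to
  pooled t or Mann–Whitney U, and linear regression against QRS duration.

## Worked example

Generate the default slab phantom (2.8 mm isotropic voxels, 40 frames/cycle,
VENC 120 cm/s, a late-filling-dominant waveform with an 8 cm/s residual
pre-systolic speed) and analyze it:

```sh
ventriflow phantom --out demo/data
ventriflow run --data demo/data --out demo/results
```

which prints:

```
phantom written to demo/data (EDV 26.7 ml, ESV 16.9 ml)
QC PASS: inflow 18.3 ml, outflow 18.3 ml, discrepancy 0.0%
  direct_flow                 9.83 ml   KE@ED   0.0334 mJ   KE/ml@ED   3.392 uJ/ml
  direct_flow_e               4.21 ml   KE@ED   0.0143 mJ   KE/ml@ED   3.392 uJ/ml
  direct_flow_a               5.62 ml   KE@ED   0.0191 mJ   KE/ml@ED   3.392 uJ/ml
  retained_inflow             8.43 ml   KE@ED   0.0286 mJ   KE/ml@ED   3.392 uJ/ml
  retained_inflow_e           0.00 ml   KE@ED   0.0000 mJ   KE/ml@ED   0.000 uJ/ml
  retained_inflow_a           8.43 ml   KE@ED   0.0286 mJ   KE/ml@ED   3.392 uJ/ml
  delayed_ejection_flow       8.43 ml   KE@ED   0.0286 mJ   KE/ml@ED   3.392 uJ/ml
  residual_volume             0.00 ml   KE@ED   0.0000 mJ   KE/ml@ED   0.000 uJ/ml
```

Reading this: of the 26.7 ml end-diastolic volume, 9.83 ml entered during
this diastole and is ejected in the following systole (Direct Flow), of
which 4.21 ml entered during early filling. Inflow and outflow volumes agree
exactly, so the dataset passes the 15 % quality-control rule. Because the
phantom's velocity field is spatially uniform, every non-empty component has
the same KE/ml at ED (½·1060 kg/m³·(0.08 m/s)² = 3.392 µJ/ml) — and all of
these numbers equal the phantom's closed-form truth table (`demo/data/truth.csv`)
to machine precision. Per-frame KE curves land in `demo/results/ke_curves.csv`.

Group statistics run from a tidy per-subject CSV (one row per subject with a
`group` column, a `qrs_duration` column and one column per parameter):

```sh
ventriflow stats --subjects subjects.csv --out report/
```

Library use mirrors the CLI: `ventriflow.generate_slab_phantom`,
`ventriflow.analyze`, `ventriflow.compare_groups`, etc.; see `docs/methods.md`
for the model details and design choices.

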
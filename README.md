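# avflow

Computational haemodynamics toolkit for arterio-venous fistula (AVF)
studies: pulsatile inflow synthesis, 0D Windkessel outlet networks and
their calibration, wall-shear-stress unsteadiness analysis, and
time-averaged oxygen-flux pathology mapping — with seeded synthetic-data
generators standing in for a 3D CFD solver so every stage runs at desk
scale.

## What is in the box

| module | contents |
| --- | --- |
| `avflow.inflow` | Fourier waveforms, `fourier_fit`, Reynolds scaling (`scale_to_peak_reynolds`), Womersley number and the Womersley radial velocity profile |
| `avflow.lumped` | RCR Windkessel terminals, the three-outlet 0D network (`simulate_network`, RK4 + numba), `dc_flow_split`, windowed flow splits (WT/WS/WD) |
| `avflow.calibration` | the pressure/flow mismatch cost (`cost_phi`), Nelder-Mead Windkessel optimisation, internal-element identification, and the outer calibration loop against a pluggable surrogate |
| `avflow.wall_analysis` | surface meshes, ring-averaged WSS magnitude, windowed PSD, snapshot POD with 96%-energy mode counting |
| `avflow.transport_maps` | Henry's-law concentrations, lumen-to-wall normal oxygen flux, quad-colour pathology classification, per-region area percentages, shear-rate exposure fractions |
| `avflow.geometry` | centreline resampling, discrete curvature, Dean number, five-section radius averaging |
| `avflow.synthetic` | seeded generators for every pipeline input, with recorded ground truth |
| `avflow.io` | CSV/JSON/ascii-PLY/HDF5 plumbing, packaged Windkessel parameter fixture (`load_table1`) |
| `avflow.cli_io` | YAML-configured pipeline and the `avflow` CLI |

Units: SI internally; Windkessel parameters and network traces use
clinical units (mmHg, mL/s; 1 mmHg = 133.322 Pa).

## CLI

```sh
avflow demo --seed 0 --outdir avflow_demo     # full pipeline + report
avflow synth --what inflow --out inflow.json  # individual generators
avflow simulate0d --column P1-IN --out network.csv
avflow calibrate --seed 0 --perturb 0.2 --out calib.json
avflow wss-analyze --mesh mesh.ply --field wss.h5 --rings mesh.rings.json --out wss.json
avflow report --config pipeline.yaml          # YAML-configured run
```

`avflow demo` writes `report.json` / `report.md` containing the
venous:arterial flow splits per analysis window, PSD summaries, POD mode
counts at 96% energy, and pathology area percentages. Reruns with the
same seed are byte-identical.

## Library example

```python
from avflow import (GeneratorConfig, gen_inflow_waveform, simulate_network,
                    dc_flow_split, window_flow_split, WINDOW_WT, InternalElements)
from avflow.io import load_table1

inflow = gen_inflow_waveform(GeneratorConfig(seed=0)).scaled(1e6)  # mL/s
wk = load_table1("P1-IN")
internal = InternalElements(L1A=1e-2, L2A=1.5e-2, L1V=2e-2,
                            R1A=5e-4, R2A=1e-3, R1V=8e-4)
sol = simulate_network(inflow, wk, internal, dt=1e-4, P_init="dc")
print(window_flow_split(sol, WINDOW_WT))   # ~ (66, 34)
print(dc_flow_split(wk))                    # 0.658...
```

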
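# mwimap

Myelin water mapping from MRI, two ways — and the statistics to compare
them.

Myelin-associated water can be quantified from multi-echo T2 relaxation
data as the **myelin water fraction (MWF)**: the T2 spectrum is
recovered by regularized non-negative least squares with stimulated-echo
(EPG) correction, and MWF is the spectral mass with 15 ms < T2 < 40 ms.
A faster steady-state alternative, **mcDESPOT**, fits a multi-pool
exchange model to multi-flip-angle SPGR and phase-cycled bSSFP data by
stochastic region contraction (SRC) and reports the myelin pool fraction
**f_M**. The two metrics are often used interchangeably, but they differ
systematically — published normative tables show f_M − MWF = +6.2
percentage points over brain WM&GM and −3.4 over the whole cervical
cord — and the mcDESPOT fit is known to be degenerate.

`mwimap` implements both arms end to end, plus:

* **EPG engine** (`mwimap.epg`) — CPMG echo amplitudes for arbitrary
  refocusing angle, validated against brute-force isochromat simulation;
* **T2 spectrum inversion** (`mwimap.t2spectrum`) — χ²-targeted
  regularized NNLS (factor 1.02), per-voxel flip-angle estimation over
  the 8-angle [90°, 180°] search, MWF maps;
* **steady-state models** (`mwimap.ssmodels`) — SPGR / IRSPGR / bSSFP
  for 1–3 pools with first-order exchange, exact matrix-exponential
  propagation, batched for fitting;
* **DESPOT1-HIFI** (`mwimap.despot1`) — joint T1/M0/flip-angle-scale
  mapping from SPGR + IRSPGR;
* **mcDESPOT SRC** (`mwimap.mcdespot`) — f_M with the published
  parameter bounds, per-parameter dispersion reported alongside every
  estimate;
* **digital phantoms** (`mwimap.phantom`) — brain- and cord-like
  subjects whose ROI truth is seeded from the published normative
  table, with Rician noise, B1/off-resonance fields, between-subject
  variability and focal lesions;
* **cohort statistics** (`mwimap.cohortstats`) — mean/SD atlases, ROI
  tables, paired tests, Bland–Altman agreement, Z-score deficiency maps
  with the 0.75 coefficient-of-variation mask.

The study itself lives in `analysis/` as numbered scripts
(01 simulate … 05 lesion Z-scores), each a thin driver over the library
that prints its finding and writes tables to `results/`.

## Worked example

Fit one noiseless two-pool voxel (15% myelin water, refocusing angle
171° from a B1 scale of 0.95) and read off the spectrum summary:

```python
import numpy as np
from mwimap import EchoTrainSpec, epg_decay, fit_mwf_signal

spec = EchoTrainSpec(te_first=10, delta_te=10, n_echoes=32, tr=1501)
signal = (0.15 * epg_decay(t2=20, t1=450, alpha=171, spec=spec)
          + 0.85 * epg_decay(t2=80, t1=1000, alpha=171, spec=spec))
res = fit_mwf_signal(signal, spec)
print(f"MWF = {res.mwf:.4f}, alpha_hat = {res.alpha_hat:.2f} deg")
```

```
MWF = 0.1451, alpha_hat = 171.05 deg
```

The estimate sits 0.5 percentage points below truth — the documented
discretization bias of the 40-point log grid with exclusive window
edges — and the stimulated-echo correction recovers the refocusing angle
to 0.05°. The same pipeline applied to a noiseless cord phantom seeded
from the normative table returns a whole-cord mean MWF of 21.6% against
the 22.1% printed seed value (`analysis/02_fit_mwf_maps.py`).

Running the steady-state arm on the same tissue
(`analysis/03_fit_steady_state.py`) illustrates the contrast between the
two methods: DESPOT1-HIFI recovers T1 and the flip-angle scale exactly,
while the SRC f_M estimate for a noiseless voxel with true f_M = 0.15
comes back at 0.22 ± 0.09 (mean ± retained-set dispersion over ten
seeds) — the fit degeneracy, reported rather than hidden.

There is also a CLI (`mwimap simulate`, `fit-grase`, `fit-despot1`,
`fit-mcdespot`, `atlas`, `zscore`, `run-all`) for file-based workflows
on NIfTI volumes with JSON protocol sidecars.

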
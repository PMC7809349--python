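# Methods

`mwimap` implements two quantification arms for myelin-associated water in
brain and cervical spinal cord MRI, the digital phantoms used to exercise
them, and the normative-atlas statistics used to compare them. This note
records the models, the parameter choices and the numerical decisions in
enough detail to re-derive them.

## Multi-echo T2 arm (MWF)

### Signal model

A CPMG/GRASE echo train is modelled with the extended phase graph (EPG)
formalism: an ideal 90° excitation, `n_echoes` refocusing pulses of angle
α about the CPMG axis, crusher dephasing of one coherence order per half
echo spacing, T2 decay of transverse (F) states and T1 decay plus
equilibrium regrowth of longitudinal (Z) states between pulses. The echo
amplitude is the F₀ state at each echo time. For α < 180° the train
contains stimulated-echo pathways; the EPG recursion accounts for them
exactly (the test suite checks agreement with a brute-force
discrete-isochromat Bloch simulation to 10⁻⁶ per echo). Dephasing orders
are truncated at `n_echoes + 1`, which is exact for this pulse count.
Echo amplitudes are invariant under α → 360° − α, so refocusing angles
above 180° (B1 scale > 1) fold back into the modelled range.

### Inversion

Each voxel's decay curve is inverted onto a fixed grid of 40 T2 values
logarithmically spaced from 15 to 2000 ms (inclusive endpoints) by
non-negative least squares. Basis matrices hold T1 fixed at 1000 ms
(`t1_fixed`, exposed): the multi-component T2 analysis does not attempt
to resolve per-component T1, and at refocusing angles near 180° the
longitudinal pathways contribute little.

The refocusing angle is estimated per voxel (stimulated-echo correction):
the unregularized NNLS residual is evaluated on 8 candidate bases
linearly spaced over [90°, 180°] (endpoints included), the minimizing
candidate is refined by parabolic interpolation of the residual, and the
estimate is polished by a golden-section search of the residual over the
bracketing interval. Refinement-stage bases are quantized to a 0.025°
lattice so they are shared across voxels through the basis cache;
parabolic interpolation alone leaves ~2° error on this sharply curved
residual landscape, which is enough to bias MWF visibly. Ties break
toward the larger angle; the search is fully deterministic.

Regularization follows the minimum-energy convention: rows `μ·I` are
appended to the basis and μ is found by bisection on log μ so that the
data misfit χ²(μ) is inflated into `[1.02, 1.025]` times the
unregularized minimum (the target factor is 1.02; the 0.005 band is the
accepted numerical tolerance of the search). χ²(μ) is monotone in μ, so
the bisection always terminates. The signal is normalized to unit energy
inside the search, making the returned spectrum shape — and hence MWF —
exactly invariant under signal scaling. When the unregularized misfit is
numerically zero (noiseless, consistent data) no finite μ can achieve the
inflation target; the unregularized solution is returned with μ = 0 and
the voxel is flagged in a QC map.

MWF is the spectrum mass with 15 ms < T2 < 40 ms divided by total mass,
with strictly exclusive window edges: grid points exactly at 15 or 40 ms
do not count as myelin water. Because the grid starts exactly at 15 ms,
reconstruction mass that lands in the first bin is excluded; this
contributes, together with the representation of off-grid T2 values by
neighbouring bins, a small systematic underestimate (~0.5 percentage
points for the default tissues) that is visible in all noiseless
recovery numbers.

### Identifiability at the default SNR

With noise defined as mean white-matter first-echo signal divided by SNR,
deleting the myelin pool entirely from a two-pool train (f = 0.15,
T2 = 20/80 ms, 32 echoes at ΔTE = 10 ms) changes χ² by only ≈ 2.5×10⁻⁴
(unit first-echo signal), while the noise χ² at SNR 100 is ≈ 2.2×10⁻³.
The short-T2 pool is therefore only ~2σ identifiable per voxel at
SNR 100, and no voxel-wise estimator can be precise there: the measured
median absolute MWF error is ≈ 0.08 at SNR 100 and falls below 0.02 only
at SNR of several hundred (see `analysis/02_fit_mwf_maps.py`). The
acquisitions being emulated use large acquired voxels precisely to buy
that SNR. The phantom default SNRs (100 brain, 60 cord) are conventional
placeholder values, kept as defaults and documented rather than tuned;
consequences for the end-to-end lesion experiment are reported honestly
by `analysis/05_lesion_zscores.py` (at SNR 100 the atlas coefficient of
variation exceeds the 0.75 mask almost everywhere and detection
collapses; noiselessly the pipeline flags ~100% of the lesion core).

## Steady-state arm (f_M)

### Signal models

SPGR, IRSPGR and bSSFP signals are computed for one, two (exchanging) or
three pools. The two exchanging pools are myelin water and free water;
exchange is first-order with myelin residence time τ (`k_mf = 1/τ`,
reverse rate from detailed balance so equilibrium fractions are
stationary). The optional third pool is non-exchanging CSF.

* SPGR: perfect spoiling; the longitudinal steady state of the coupled
  relaxation–exchange system is solved with exact 2×2 matrix
  exponentials; the single-pool limit is the Ernst equation.
* IRSPGR: single-shot approximation — an ideal inversion of equilibrium
  magnetization recovers for TI under the coupled longitudinal generator,
  and the per-pool recovered fraction scales the SPGR steady-state
  readout. The single-pool magnitude is |1 − 2e^(−TI/T1)| × S_SPGR, with
  its null at TI = T1 ln 2, and approaches the plain SPGR signal as
  TI → ∞. Inversion efficiency is fixed at 1.
* bSSFP: the periodic steady state of the full transverse + longitudinal
  system. The state is propagated in the complex (M+, M−, Mz) basis, in
  which free evolution is block diagonal with 2×2 blocks per component
  (closed-form matrix exponentials) and the RF pulse is the standard
  3×3 complex mixing matrix applied pool-wise; the steady state is one
  6×6 linear solve per flip angle, batched over parameter samples. RF
  phase cycling of φ degrees per TR enters as an apparent off-resonance
  φ/(360·TR) added to the tissue Δf. The signal is read out at the echo
  time (TR/2 in the emulated protocols). CSF, being non-exchanging,
  decouples and is handled as a scalar single-pool block.

All three models accept a `te` argument (default 0, i.e. signal directly
after the pulse); the phantom applies the protocol TE to bSSFP, where TE
interacts with off-resonance, and leaves SPGR/IRSPGR at te = 0, where TE
decay is a pure per-pool scale absorbed by M0 — keeping the DESPOT1 fit
model-consistent. Tests verify the closed-form single-pool limits, the
no-exchange pool-sum limit, Δf-periodicity with period 1/TR, and
agreement with an independent pulse-by-pulse Bloch iteration (scipy
`expm`) to 10⁻⁹.

### DESPOT1-HIFI

T1, M0 and the flip-angle scale κ are fitted per voxel from the
multi-flip-angle SPGR series plus one IRSPGR measurement. For fixed κ the
classical DESPOT1 linearization gives (T1, M0) in closed form; κ is found
by a 41-point grid scan of the profile cost followed by golden-section
refinement. The magnitude IRSPGR model has two exact solution branches
(the sign of the recovery factor is lost): the physical branch with
T1 > TI/ln 2 and an aliased twin at shorter T1 with κ inflated by ~40%.
The fitter prefers local minima on the long-T1 branch — the protocols
place TI below the tissue null by design — and accepts the short branch
only if nothing else fits. Noiseless single-pool recovery is then exact
to optimizer tolerance; on two-pool phantom volumes the κ map is
recovered with 0.04% RMSE noiselessly and ≈ 1.9% at SNR 100. An optional
spatial regularization of the κ map (median + Gaussian, off by default)
is available for low-SNR sessions.

### mcDESPOT by stochastic region contraction

f_M is estimated by fitting the two- or three-pool model (three-pool
default) to the normalized SPGR and bSSFP data — SPGR divided by its own
mean, the phase-cycle stack by its joint mean, removing M0 and receive
gain — with κ fixed from DESPOT1. The optimizer draws `n_samples = 5000`
uniform points in the current parameter box, keeps the `n_retain = 50`
best (previously retained points re-enter the pool, so the retained cost
is non-increasing), and contracts the box to the retained min–max
envelope expanded by γ = 1.05 about its centre, clipped to the original
bounds, stopping when every width is below ε = 0.01 of its initial value
or after `max_iter = 8` iterations. All hyperparameters are exposed. The
search box is the published one — f_M ∈ [10⁻⁸, 0.35], T1_myelin
[300, 650] ms, T2_myelin [1, 30] ms, T1_free [700, t1_max] ms, T2_free
[50, 165] ms, τ [25, 600] ms — with t1_max defaulting to 2000 ms (the
upper free-water T1 bound is not printed anywhere), CSF bounds
f_csf [0, 0.35], T1_csf [2000, 5000] ms, T2_csf [150, 800] ms by
three-pool convention, and Δf bounded by ± half the bSSFP band, 1/(2 TR).
Per-voxel seeds derive deterministically from (seed, voxel index).

This inverse problem is degenerate: on a noiseless two-pool brain-protocol
voxel an independent local optimizer reaches residuals below 10⁻⁵ (sum of
squares of normalized signals) across essentially the whole f_M box, so
the data constrain f_M only through a very shallow cost valley. The SRC
point estimate (retained-set mean) is consequently biased upward
(≈ 0.22 for truth 0.15) with seed-to-seed scatter, mirroring the known
instability and bias of this estimator family. The fitter therefore
reports the retained-set dispersion per parameter alongside every point
estimate, and the analysis scripts present both.

## Digital phantoms

Geometry is procedural. Brain: nested ellipsoids — CSF rim, cortical
ribbon, white-matter core hosting ventricles, anterior and posterior
callosal structures, posterior-capsule blobs, and caudate/thalamus
nuclei. Cord: an axial circle with a two-lobed "butterfly" grey-matter
core (tuned to ≈ 21% of the cord cross-section, matching the published
WM/GM voxel-count ratio), dorsal-column and lateral-funiculus wedges, and
a CSF rim, repeated along z. Minimum grids: 16³ (brain), 32×32×8 (cord);
every labelled ROI must be non-empty or generation fails.

Ground-truth myelin fractions are seeded from the published normative ROI
MWF means (e.g. genu 9.1%, splenium 13.4%, posterior internal capsule
17.6%, cortical GM 3.7%, cord GM 15.7%, dorsal column 25.6%), with a
smooth mean-centred texture (SD 0.008) so each ROI mean hits its target
exactly. Remaining defaults: T2_myelin 20 ms, T2_free 80 ms (brain) /
70 ms (cord), T1_myelin 450 ms, T1_free 1000 ms, τ 150 ms — all inside
the steady-state search box; CSF T1 3500 ms, T2 1800 ms; proton density
0.85 (WM) / 0.90 (GM) / 1.0 (CSF). B1 is a smooth random field
1 + 0.1·g (range [0.9, 1.1]); off-resonance ±20 Hz (brain) / ±15 Hz
(cord), both low-order cosine fields.

Noise is Rician: complex Gaussian channel noise of one σ per dataset —
mean white-matter first-echo (GRASE) or mean white-matter SPGR signal
(steady state) divided by SNR — followed by magnitude. Cohorts apply
per-subject multiplicative lognormal jitter (unit mean, CV 0.05 default,
spatially constant, independent per parameter map) plus subject-specific
B1/off-resonance draws; at CV = 0 subjects are bit-identical, which the
atlas tests use to exercise the zero-SD guard. Lesions are spheres at
random white-matter centres that remove a fraction of the local myelin
fraction (default 50%) and lengthen free-water T2 (+20 ms).

The generator emulates: between-region contrast, between-subject
variability, instrumental fields, magnitude noise, focal lesions. It does
not emulate realistic anatomy, partial-volume boundary mixing beyond
voxel-level label assignment, motion, k-space artefacts, or spatially
varying pool relaxation times within an ROI — so passing tests show the
estimators work under the assumed statistical structure, not that they
are robust to everything real data contains.

## Cohort statistics

Atlases are voxel-wise mean and sample SD (n − 1) over aligned subject
maps, cropped to voxels finite in every subject. ROI tables report mean,
SD and voxel count of finite voxels per label set; metric values are
fractions internally and percentages (one decimal) when rendered.
Paired comparisons use the classical two-tailed paired t test (df = n−1),
with explicit zero-variance handling (identical samples → t = 0, p = 1;
constant nonzero difference → t = ±∞, p = 0); tests check it against
exact sign-flip enumeration. Bland–Altman agreement reports
bias = mean(b − a) and limits bias ± 1.96·SD (sample SD). Z maps are
(subject − atlas mean)/atlas SD on the coverage mask, excluding voxels
with atlas CoV = SD/mean > 0.75 (strict), non-positive mean, or zero SD;
deficiency is Z ≤ −1.96. Histograms use fixed-width bins over defined Z
values.

## Problem sizes

The test suite and the reproduction script run the recovery experiments
at desk scale: 16³ brain and 32×32×8 cord grids, cohorts of 7, 200-voxel
precision sweeps, 10-seed SRC experiments. These sizes were chosen so the
full suite completes in a few minutes while keeping every ROI populated
and every statistical contrast measurable.

## Known limitations

* Voxel-wise MWF at the default phantom SNR is imprecise for fundamental
  identifiability reasons (quantified above), which propagates to the
  SNR-100 lesion Z-score experiment.
* The SRC point estimate inherits the degeneracy of the multi-pool
  steady-state model; dispersion maps are the honest companion output.
* The IRSPGR single-shot approximation ignores shot structure and
  readout-train transients.
* The EPG model assumes an ideal excitation and slice profile; only
  refocusing imperfection is modelled.
* The mono-exponential `t1_single` truth map is a linear pool-T1 mix,
  an approximate reference rather than the exact effective T1.
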
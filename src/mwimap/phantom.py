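"""Digital brain and spinal-cord phantoms for myelin water imaging.

The study data these phantoms stand in for cannot be shared, so synthetic
subjects reproduce the statistical structure the downstream analyses
assume: per-voxel two-pool tissue (a fast-relaxing myelin water pool in
slow exchange with free water), region-of-interest myelin fractions seeded
from the published normative ROI table, smooth B1 (flip-angle scale) and
off-resonance fields, Rician magnitude noise, multiplicative
between-subject variability and optional focal demyelinating lesions.

Geometry is procedural: nested ellipsoids for the brain (white matter core
with callosal and capsular structures, deep grey nuclei, cortical ribbon,
CSF), and a cylinder with a butterfly grey-matter core for the cervical
cord. It is deliberately schematic — the point is statistics, not anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .epg import EchoTrainSpec, epg_decay_batch
from .reference import NORMATIVE_ROI_TABLE
from .ssmodels import SteadyStateProtocol, _bssfp_batch, _irspgr_batch, _spgr_batch

__all__ = [
    "PhantomTruth",
    "CohortSpec",
    "LesionSpec",
    "GraseDataset",
    "McDespotDataset",
    "SubjectData",
    "BRAIN_LABELS",
    "CORD_LABELS",
    "ROI_GROUPS",
    "make_phantom",
    "simulate_grase",
    "simulate_mcdespot",
    "make_cohort",
    "rician",
]

# tissue label codes
BRAIN_LABELS = {
    "csf": 1,
    "cortical_gm": 2,
    "caudate": 3,
    "thalamus": 4,
    "wm": 5,
    "genu": 6,
    "splenium": 7,
    "posterior_internal_capsule": 8,
}
CORD_LABELS = {
    "csf": 1,
    "cord_gm": 2,
    "cord_wm_other": 3,
    "dorsal_column": 4,
    "lateral_funiculi": 5,
}

# aggregate ROIs (analogy to the published ROI menu), per phantom kind
ROI_GROUPS = {
    "brain": {
        "genu": {6},
        "splenium": {7},
        "posterior_internal_capsule": {8},
        "caudate": {3},
        "thalamus": {4},
        "cortical_gm": {2},
        "all_wm": {5, 6, 7, 8},
        "all_gm": {2, 3, 4},
        "all_wm_gm": {2, 3, 4, 5, 6, 7, 8},
        "csf": {1},
    },
    "cord": {
        "cord_gm": {2},
        "dorsal_column": {4},
        "lateral_funiculi": {5},
        "cord_wm": {3, 4, 5},
        "whole_cord": {2, 3, 4, 5},
        "csf": {1},
    },
}

# labels counted as white matter when scaling the noise level
_WM_LABELS = {"brain": (5, 6, 7, 8), "cord": (3, 4, 5)}

# default truth values (ms) — inside the steady-state fitting bounds
T2_MYELIN = 20.0
T2_FREE = {"brain": 80.0, "cord": 70.0}
T1_MYELIN = 450.0
T1_FREE = 1000.0
TAU_MYELIN = 150.0
T1_CSF = 3500.0
T2_CSF = 1800.0
M0 = {"wm": 0.85, "gm": 0.90, "csf": 1.0}

DEFAULT_SNR = {"brain": 100.0, "cord": 60.0}


@dataclass
class PhantomTruth:
    """Ground-truth parameter maps of one synthetic subject.

    All maps share one voxel grid. ``f_m_true`` is the myelin water
    fraction; relaxation times and the myelin residence time
    ``tau_myelin`` are in ms; ``kappa`` is the B1 scale (actual/nominal
    flip angle); ``delta_f`` is off-resonance in Hz; ``t1_single`` is the
    effective mono-exponential T1 reference. ``lesion_mask`` marks voxels
    modified by focal lesions (None for healthy subjects).
    """

    kind: str
    labels: np.ndarray
    f_m_true: np.ndarray
    t1_myelin: np.ndarray
    t2_myelin: np.ndarray
    t1_free: np.ndarray
    t2_free: np.ndarray
    tau_myelin: np.ndarray
    t1_single: np.ndarray
    m0: np.ndarray
    kappa: np.ndarray
    delta_f: np.ndarray
    lesion_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = self.labels.shape
        for name in ("f_m_true", "t1_myelin", "t2_myelin", "t1_free", "t2_free",
                     "tau_myelin", "t1_single", "m0", "kappa", "delta_f"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} not on the common voxel grid")
        tissue = self.labels > 0
        if np.any((self.f_m_true < 0) | (self.f_m_true > 1)):
            raise ValueError("f_m_true must lie in [0, 1]")
        for name in ("t1_myelin", "t2_myelin", "t1_free", "t2_free", "tau_myelin"):
            if np.any(getattr(self, name)[tissue] <= 0):
                raise ValueError(f"{name} must be positive in tissue")
        if np.any((self.kappa[tissue] <= 0) | (self.kappa[tissue] > 1.5)):
            raise ValueError("kappa must lie in (0, 1.5]")

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.labels > 0

    def roi_mask(self, roi: str) -> np.ndarray:
        codes = ROI_GROUPS[self.kind][roi]
        return np.isin(self.labels, list(codes))


@dataclass(frozen=True)
class CohortSpec:
    """Cohort generation parameters.

    ``between_subject_cv`` is the coefficient of variation of the
    multiplicative lognormal jitter applied to each subject's truth maps;
    ``snr`` is mean white-matter reference signal over the Gaussian channel
    sigma.
    """

    n_subjects: int
    between_subject_cv: float = 0.05
    snr: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if self.between_subject_cv < 0:
            raise ValueError("between_subject_cv must be non-negative")


@dataclass(frozen=True)
class LesionSpec:
    """Focal lesion model: spheres of reduced myelin fraction.

    ``f_m_reduction`` is the fraction of the local true myelin fraction
    removed inside the lesion; ``t2_free_increase`` (ms) is added to the
    free-water T2 there.
    """

    n_lesions: int = 1
    radius_vox: tuple = (2.0, 3.0)
    f_m_reduction: float = 0.5
    t2_free_increase: float = 20.0

    def __post_init__(self) -> None:
        if not 0 <= self.f_m_reduction <= 1:
            raise ValueError("f_m_reduction must lie in [0, 1]")
        if self.n_lesions < 0 or self.radius_vox[0] > self.radius_vox[1]:
            raise ValueError("invalid lesion spec")


@dataclass
class GraseDataset:
    """4-D multi-echo magnitude volume (echo index on the last axis)."""

    echoes: np.ndarray
    spec: EchoTrainSpec
    snr: float
    seed: int


@dataclass
class McDespotDataset:
    """One steady-state session: SPGR stack, one IRSPGR, bSSFP per cycle."""

    spgr: np.ndarray  # (..., n_spgr_fas)
    irspgr: np.ndarray  # (...)
    bssfp: dict  # phase cycle (deg) -> (..., n_bssfp_fas)
    protocol: SteadyStateProtocol
    snr: float
    seed: int


@dataclass
class SubjectData:
    truth: PhantomTruth
    grase: GraseDataset | None = None
    mcdespot: McDespotDataset | None = None


def _smooth_field(dims, rng, n_modes: int = 3) -> np.ndarray:
    """Smooth random field normalized to [-1, 1] (low-order cosine modes)."""
    grids = np.meshgrid(
        *[np.linspace(-1.0, 1.0, d) for d in dims], indexing="ij"
    )
    f = np.zeros(dims)
    for _ in range(n_modes):
        k = rng.uniform(0.5, 1.5, size=3)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        f += amp * np.cos(np.pi * sum(k[i] * grids[i] for i in range(3)) + phase)
    peak = np.max(np.abs(f))
    return f / peak if peak > 0 else f


def _ellipsoid(coords, center, radii) -> np.ndarray:
    return sum(
        ((coords[i] - center[i]) / radii[i]) ** 2 for i in range(3)
    ) <= 1.0


def _brain_labels(dims) -> np.ndarray:
    L = BRAIN_LABELS
    u = np.meshgrid(*[np.linspace(-1.0, 1.0, d) for d in dims], indexing="ij")
    r = np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
    labels = np.zeros(dims, dtype=np.int16)
    labels[r <= 0.92] = L["csf"]
    labels[r <= 0.84] = L["cortical_gm"]
    labels[r <= 0.62] = L["wm"]
    wm = labels == L["wm"]
    # ventricles: central CSF slab (y = anterior-posterior axis)
    vent = _ellipsoid(u, (0.0, 0.0, 0.0), (0.13, 0.30, 0.13)) & wm
    # callosal genu (anterior) and splenium (posterior)
    genu = _ellipsoid(u, (0.0, 0.40, 0.0), (0.26, 0.15, 0.14)) & wm
    splen = _ellipsoid(u, (0.0, -0.40, 0.0), (0.26, 0.15, 0.14)) & wm
    pic = (
        _ellipsoid(u, (0.38, -0.10, 0.0), (0.15, 0.22, 0.18))
        | _ellipsoid(u, (-0.38, -0.10, 0.0), (0.15, 0.22, 0.18))
    ) & wm
    caud = (
        _ellipsoid(u, (0.22, 0.18, 0.12), (0.14, 0.14, 0.14))
        | _ellipsoid(u, (-0.22, 0.18, 0.12), (0.14, 0.14, 0.14))
    ) & wm
    thal = (
        _ellipsoid(u, (0.18, -0.14, -0.10), (0.16, 0.16, 0.16))
        | _ellipsoid(u, (-0.18, -0.14, -0.10), (0.16, 0.16, 0.16))
    ) & wm
    for mask, name in [(vent, "csf"), (genu, "genu"), (splen, "splenium"),
                       (pic, "posterior_internal_capsule"), (caud, "caudate"),
                       (thal, "thalamus")]:
        labels[mask] = L[name]
    return labels


def _cord_labels(dims) -> np.ndarray:
    L = CORD_LABELS
    nx, ny = dims[0], dims[1]
    x = np.arange(nx)[:, None] - (nx - 1) / 2.0
    y = np.arange(ny)[None, :] - (ny - 1) / 2.0
    scale = min(nx, ny) / 32.0
    r_cord = 6.4 * scale
    r = np.sqrt(x**2 + y**2)
    sl = np.zeros((nx, ny), dtype=np.int16)
    sl[r <= r_cord + 2.0 * scale] = L["csf"]
    cord = r <= r_cord
    # butterfly grey matter: two para-median lobes (~22% of the cord area)
    gm = (
        (((x - 1.9 * scale) / (1.55 * scale)) ** 2 + ((y - 0.4 * scale) / (2.7 * scale)) ** 2 <= 1.0)
        | (((x + 1.9 * scale) / (1.55 * scale)) ** 2 + ((y - 0.4 * scale) / (2.7 * scale)) ** 2 <= 1.0)
    ) & cord
    wm = cord & ~gm
    ang = np.arctan2(x, y)  # 0 at +y (dorsal)
    dorsal = wm & (np.abs(ang) <= np.deg2rad(45)) & (y > 0)
    lateral = wm & (np.abs(np.abs(ang) - np.pi / 2) <= np.deg2rad(45))
    sl[wm] = L["cord_wm_other"]
    sl[dorsal] = L["dorsal_column"]
    sl[lateral & (sl != L["dorsal_column"])] = L["lateral_funiculi"]
    sl[gm] = L["cord_gm"]
    return np.repeat(sl[:, :, None], dims[2], axis=2)


# ROI truth means: analogous published MWF means (fractions)
def _truth_means(kind: str) -> dict:
    t = NORMATIVE_ROI_TABLE["mwf_mean"] / 100.0
    if kind == "brain":
        return {
            "cortical_gm": t["cortical_gm"],
            "caudate": t["caudate"],
            "thalamus": t["thalamus"],
            "wm": t["all_wm"],
            "genu": t["genu"],
            "splenium": t["splenium"],
            "posterior_internal_capsule": t["posterior_internal_capsule"],
        }
    return {
        "cord_gm": t["cord_gm"],
        "cord_wm_other": 0.235,  # residual WM, so all-WM lands near its mean
        "dorsal_column": t["dorsal_column"],
        "lateral_funiculi": t["lateral_funiculi"],
    }


def make_phantom(kind: str, dims=None, seed: int = 0):
    """Build one ground-truth subject.

    Parameters
    ----------
    kind : {"brain", "cord"}
    dims : tuple of 3 ints
        Voxel grid; at least 16^3 (brain) or 32 x 32 x 8 (cord).
    seed : int
        Drives the within-ROI texture and the smooth B1/off-resonance
        fields; the same seed reproduces the subject bit-for-bit.

    Returns
    -------
    (PhantomTruth, labels)
    """
    if kind not in ("brain", "cord"):
        raise ValueError(f"unknown phantom kind: {kind!r}")
    if dims is None:
        dims = (16, 16, 16) if kind == "brain" else (32, 32, 8)
    dims = tuple(int(d) for d in dims)
    min_dims = (16, 16, 16) if kind == "brain" else (32, 32, 8)
    if any(d < m for d, m in zip(dims, min_dims)):
        raise ValueError(f"dims {dims} too small to host the {kind} ROI set")

    labels = _brain_labels(dims) if kind == "brain" else _cord_labels(dims)
    label_map = BRAIN_LABELS if kind == "brain" else CORD_LABELS
    for name, code in label_map.items():
        if not np.any(labels == code):
            raise ValueError(f"dims {dims} too small: ROI {name!r} is empty")

    rng = np.random.default_rng(seed)
    texture = 0.008 * _smooth_field(dims, rng, n_modes=4)
    f_m = np.zeros(dims)
    means = _truth_means(kind)
    for name, mean in means.items():
        m = labels == label_map[name]
        # mean-centred texture so each ROI mean hits its target exactly
        f_m[m] = mean + texture[m] - texture[m].mean()
    f_m = np.clip(f_m, 0.0, 1.0)
    f_m[labels == label_map["csf"]] = 0.0
    f_m[labels == 0] = 0.0

    tissue = labels > 0
    csf = labels == label_map["csf"]
    gm_codes = {"brain": (2, 3, 4), "cord": (2,)}[kind]
    gm = np.isin(labels, gm_codes)
    wm = tissue & ~csf & ~gm

    def fill(base, csf_val):
        out = np.zeros(dims)
        out[tissue] = base
        out[csf] = csf_val
        return out

    t1_m = fill(T1_MYELIN, T1_MYELIN)
    t2_m = fill(T2_MYELIN, T2_MYELIN)
    t1_f = fill(T1_FREE, T1_CSF)
    t2_f = fill(T2_FREE[kind], T2_CSF)
    tau = fill(TAU_MYELIN, TAU_MYELIN)
    m0 = np.zeros(dims)
    m0[wm] = M0["wm"]
    m0[gm] = M0["gm"]
    m0[csf] = M0["csf"]

    kappa = 1.0 + 0.1 * _smooth_field(dims, rng)
    delta_f = (20.0 if kind == "brain" else 15.0) * _smooth_field(dims, rng)
    t1_single = f_m * t1_m + (1.0 - f_m) * t1_f

    truth = PhantomTruth(
        kind=kind, labels=labels, f_m_true=f_m,
        t1_myelin=t1_m, t2_myelin=t2_m, t1_free=t1_f, t2_free=t2_f,
        tau_myelin=tau, t1_single=t1_single, m0=m0,
        kappa=kappa, delta_f=delta_f,
    )
    return truth, labels


def rician(signal: np.ndarray, sigma: float, rng) -> np.ndarray:
    """Magnitude of the signal after complex Gaussian channel noise."""
    if sigma == 0:
        return np.abs(signal)
    re = signal + sigma * rng.standard_normal(signal.shape)
    im = sigma * rng.standard_normal(signal.shape)
    return np.hypot(re, im)


def _fold_refocus_angle(alpha: np.ndarray) -> np.ndarray:
    """Map nominal*kappa refocusing angles above 180 deg onto (0, 180].

    CPMG echo amplitudes are invariant under alpha -> 360 - alpha, so
    angles from B1 scales above 1 fold back into the modelled range.
    """
    a = np.mod(np.asarray(alpha, dtype=float), 360.0)
    return np.where(a > 180.0, 360.0 - a, a)


def _wm_sigma(reference_signal: np.ndarray, truth: PhantomTruth, snr: float) -> float:
    wm = np.isin(truth.labels, _WM_LABELS[truth.kind])
    return float(np.mean(reference_signal[wm]) / snr)


def simulate_grase(
    truth: PhantomTruth,
    echo_spec: EchoTrainSpec,
    snr: float = np.inf,
    seed: int = 0,
) -> GraseDataset:
    """Forward-simulate a multi-echo GRASE acquisition of one subject.

    Per tissue voxel the noiseless signal is
    ``m0 * (f EPG(T2_myelin) + (1 - f) EPG(T2_free))`` evaluated at the
    actual refocusing angle ``180 kappa`` degrees. The Gaussian channel
    sigma is the mean white-matter first-echo signal divided by ``snr``
    (``snr = inf``: noiseless).
    """
    dims = truth.labels.shape
    mask = truth.tissue_mask
    idx = np.nonzero(mask)
    alpha = _fold_refocus_angle(180.0 * truth.kappa[idx])
    f = truth.f_m_true[idx]
    my = epg_decay_batch(truth.t2_myelin[idx], truth.t1_myelin[idx], alpha, echo_spec)
    fr = epg_decay_batch(truth.t2_free[idx], truth.t1_free[idx], alpha, echo_spec)
    sig = truth.m0[idx] * (f * my + (1.0 - f) * fr)  # (n_echoes, n_vox)

    vol = np.zeros(dims + (echo_spec.n_echoes,))
    vol[idx] = sig.T
    if np.isfinite(snr):
        sigma = _wm_sigma(vol[..., 0], truth, snr)
        rng = np.random.default_rng(seed)
        vol = rician(vol, sigma, rng)
    return GraseDataset(echoes=vol, spec=echo_spec, snr=snr, seed=seed)


def simulate_mcdespot(
    truth: PhantomTruth,
    protocol: SteadyStateProtocol,
    snr: float = np.inf,
    seed: int = 0,
) -> McDespotDataset:
    """Forward-simulate one SPGR + IRSPGR + bSSFP steady-state session.

    Signals come from the two-pool exchange models with nominal flip
    angles scaled by the B1 map and bSSFP off-resonance from the truth
    ``delta_f`` map; bSSFP is read out at the protocol TE (TR/2), SPGR and
    IRSPGR directly after the pulse. One Gaussian sigma — mean white-matter
    SPGR signal / snr — applies to every volume of the session.
    """
    dims = truth.labels.shape
    mask = truth.tissue_mask
    idx = np.nonzero(mask)
    args = (
        truth.f_m_true[idx], np.zeros(mask.sum()),
        truth.t1_myelin[idx], truth.t1_free[idx], np.full(mask.sum(), T1_CSF),
        truth.t2_myelin[idx], truth.t2_free[idx], np.full(mask.sum(), T2_CSF),
        truth.tau_myelin[idx], truth.m0[idx],
    )
    kappa = truth.kappa[idx]
    spgr_v = _spgr_batch(*args, protocol.spgr_tr, protocol.spgr_fas, kappa)
    ir_v = _irspgr_batch(*args, protocol.irspgr_tr, protocol.irspgr_ti,
                         protocol.irspgr_fa, kappa)
    bssfp_v = {
        pc: _bssfp_batch(*args, truth.delta_f[idx],
                         protocol.bssfp_tr, protocol.bssfp_fas, pc, kappa,
                         protocol.bssfp_te)
        for pc in protocol.phase_cycles
    }

    spgr = np.zeros(dims + (len(protocol.spgr_fas),))
    spgr[idx] = spgr_v
    irspgr = np.zeros(dims)
    irspgr[idx] = ir_v
    bssfp = {}
    for pc, v in bssfp_v.items():
        vol = np.zeros(dims + (len(protocol.bssfp_fas),))
        vol[idx] = v
        bssfp[pc] = vol

    if np.isfinite(snr):
        sigma = _wm_sigma(spgr.mean(axis=-1), truth, snr)
        rng = np.random.default_rng(seed)
        spgr = rician(spgr, sigma, rng)
        irspgr = rician(irspgr, sigma, rng)
        bssfp = {pc: rician(v, sigma, rng) for pc, v in bssfp.items()}
    return McDespotDataset(spgr=spgr, irspgr=irspgr, bssfp=bssfp,
                           protocol=protocol, snr=snr, seed=seed)


def _apply_lesions(truth: PhantomTruth, spec: LesionSpec, rng) -> PhantomTruth:
    dims = truth.labels.shape
    wm = np.isin(truth.labels, _WM_LABELS[truth.kind])
    centers = np.array(np.nonzero(wm)).T
    if len(centers) == 0:
        raise ValueError("no white matter to place lesions in")
    f_m = truth.f_m_true.copy()
    t2_f = truth.t2_free.copy()
    lesion_mask = np.zeros(dims, dtype=bool)
    grids = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    for _ in range(spec.n_lesions):
        c = centers[rng.integers(len(centers))]
        radius = rng.uniform(*spec.radius_vox)
        d2 = sum((grids[i] - c[i]) ** 2 for i in range(3))
        sphere = (d2 <= radius**2) & (truth.labels > 0)
        lesion_mask |= sphere
    f_m[lesion_mask] *= 1.0 - spec.f_m_reduction
    t2_f[lesion_mask] += spec.t2_free_increase
    return replace(
        truth,
        f_m_true=f_m,
        t2_free=t2_f,
        t1_single=f_m * truth.t1_myelin + (1.0 - f_m) * truth.t1_free,
        lesion_mask=lesion_mask,
    )


def make_cohort(
    kind: str,
    dims,
    spec: CohortSpec,
    lesions: dict | None = None,
    grase_spec: EchoTrainSpec | None = None,
    ss_protocol: SteadyStateProtocol | None = None,
    simulate=("grase",),
) -> list:
    """Generate an aligned cohort of synthetic subjects with datasets.

    Each subject is the base phantom with per-parameter multiplicative
    lognormal jitter (unit mean, CV ``spec.between_subject_cv``, spatially
    constant per subject) and a subject-specific B1/off-resonance draw.
    ``lesions`` maps subject index -> LesionSpec. ``simulate`` selects the
    acquisitions to run ("grase", "mcdespot").

    Returns a list of :class:`SubjectData`.
    """
    from .reference import (
        brain_grase_protocol, brain_steady_state_protocol,
        cord_grase_protocol, cord_steady_state_protocol,
    )

    if grase_spec is None:
        grase_spec = brain_grase_protocol() if kind == "brain" else cord_grase_protocol()
    if ss_protocol is None:
        ss_protocol = (brain_steady_state_protocol() if kind == "brain"
                       else cord_steady_state_protocol())
    lesions = lesions or {}
    base, _ = make_phantom(kind, dims, seed=spec.seed)
    cohort = []
    cv = spec.between_subject_cv
    sig_ln = np.sqrt(np.log1p(cv**2))  # lognormal with unit mean, CV=cv
    for s in range(spec.n_subjects):
        rng = np.random.default_rng((spec.seed, 1, s))
        if cv > 0:
            jit = {
                name: rng.lognormal(-0.5 * sig_ln**2, sig_ln)
                for name in ("f_m_true", "t1_myelin", "t2_myelin",
                             "t1_free", "t2_free", "tau_myelin", "m0")
            }
        else:
            jit = {}
        truth = base
        if jit:
            fields = {k: getattr(base, k) * v for k, v in jit.items()}
            fields["f_m_true"] = np.clip(fields["f_m_true"], 0.0, 1.0)
            # subject-specific smooth instrumental fields
            fields["kappa"] = 1.0 + 0.1 * _smooth_field(base.labels.shape, rng)
            fields["delta_f"] = (20.0 if kind == "brain" else 15.0) * \
                _smooth_field(base.labels.shape, rng)
            truth = replace(base, **fields)
            truth = replace(
                truth,
                t1_single=truth.f_m_true * truth.t1_myelin
                + (1.0 - truth.f_m_true) * truth.t1_free,
            )
        if s in lesions:
            truth = _apply_lesions(truth, lesions[s], rng)
        subj = SubjectData(truth=truth)
        if "grase" in simulate:
            subj.grase = simulate_grase(truth, grase_spec, spec.snr,
                                        seed=int(rng.integers(2**31)))
        if "mcdespot" in simulate:
            subj.mcdespot = simulate_mcdespot(truth, ss_protocol, spec.snr,
                                              seed=int(rng.integers(2**31)))
        cohort.append(subj)
    return cohort
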
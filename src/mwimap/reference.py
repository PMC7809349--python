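"""Normative reference values and acquisition protocols.

The published normative atlas study reports, for each brain and cervical
spinal cord region of interest, the mean and SD of the multi-echo-T2 myelin
water fraction (MWF) and of the steady-state mcDESPOT myelin fraction
(f_M), together with ROI voxel counts. Those printed values are inputs
here: they seed the digital phantom's ground truth and anchor the
in-table arithmetic checks (metric biases, white-matter volume fractions).

Values are stored as percentages exactly as printed (one decimal).
"""

from __future__ import annotations

import pandas as pd

from .epg import EchoTrainSpec
from .ssmodels import SteadyStateProtocol

__all__ = [
    "NORMATIVE_ROI_TABLE",
    "normative_table",
    "brain_grase_protocol",
    "cord_grase_protocol",
    "brain_steady_state_protocol",
    "cord_steady_state_protocol",
]

# roi key, site, MWF mean %, MWF sd %, f_M mean %, f_M sd %, n voxels
_ROWS = [
    ("all_wm_gm", "brain", 5.7, 5.4, 11.9, 5.5, 1_239_957),
    ("all_wm", "brain", 8.0, 4.9, 16.8, 4.1, 538_746),
    ("all_jhu", "brain", 11.5, 4.5, 19.9, 2.7, 78_903),
    ("genu", "brain", 9.1, 2.3, 20.0, 3.0, 5_260),
    ("splenium", "brain", 13.4, 2.8, 20.4, 3.1, 7_527),
    ("corpus_callosum", "brain", 11.1, 3.0, 19.6, 3.0, 21_435),
    ("posterior_internal_capsule", "brain", 17.6, 4.0, 19.5, 1.2, 5_437),
    ("frontal_wm", "brain", 7.1, 3.5, 17.6, 3.4, 115_698),
    ("occipital_wm", "brain", 7.3, 3.2, 16.0, 3.9, 72_205),
    ("parietal_wm", "brain", 8.3, 3.7, 17.8, 3.6, 100_925),
    ("temporal_wm", "brain", 6.8, 2.9, 16.4, 3.7, 45_173),
    ("all_gm", "brain", 4.1, 5.2, 8.1, 2.7, 701_211),
    ("cortical_gm", "brain", 3.7, 4.1, 8.7, 2.8, 445_356),
    ("caudate", "brain", 3.0, 1.8, 10.0, 3.3, 8_130),
    ("thalamus", "brain", 7.4, 5.2, 13.2, 3.7, 14_105),
    ("putamen", "brain", 5.0, 3.8, 12.0, 2.6, 13_748),
    ("whole_cord", "cord", 22.1, 5.7, 18.7, 2.9, 18_673),
    ("cord_wm", "cord", 23.8, 4.4, 18.6, 3.2, 14_614),
    ("cord_gm", "cord", 15.7, 5.1, 19.0, 1.0, 4_059),
    ("dorsal_column", "cord", 25.6, 4.6, 19.2, 2.5, 5_541),
    ("lateral_funiculi", "cord", 22.8, 3.9, 18.3, 3.3, 7_235),
]

NORMATIVE_ROI_TABLE = pd.DataFrame(
    _ROWS,
    columns=["roi", "site", "mwf_mean", "mwf_sd", "fm_mean", "fm_sd", "n_voxels"],
).set_index("roi")


def normative_table(metric: str, site: str | None = None) -> pd.DataFrame:
    """Published ROI summary for one metric, in RoiTable layout.

    Parameters
    ----------
    metric : {"mwf", "fm"}
    site : {"brain", "cord"}, optional
        Restrict to one anatomical site.

    Returns
    -------
    DataFrame indexed by roi with columns mean_pct, sd_pct, n_voxels.
    """
    if metric not in ("mwf", "fm"):
        raise ValueError("metric must be 'mwf' or 'fm'")
    tab = NORMATIVE_ROI_TABLE
    if site is not None:
        tab = tab[tab["site"] == site]
    out = pd.DataFrame(
        {
            "mean_pct": tab[f"{metric}_mean"],
            "sd_pct": tab[f"{metric}_sd"],
            "n_voxels": tab["n_voxels"],
        }
    )
    return out


def brain_grase_protocol() -> EchoTrainSpec:
    """Brain 3D GRASE: TE = dTE = 8 ms, 48 echoes, TR = 1073 ms."""
    return EchoTrainSpec(te_first=8.0, delta_te=8.0, n_echoes=48, tr=1073.0)


def cord_grase_protocol() -> EchoTrainSpec:
    """Cord 3D GRASE: TE = dTE = 10 ms, 32 echoes, TR = 1501 ms."""
    return EchoTrainSpec(te_first=10.0, delta_te=10.0, n_echoes=32, tr=1501.0)


def brain_steady_state_protocol() -> SteadyStateProtocol:
    """Brain mcDESPOT session (SPGR / IRSPGR / bSSFP, 0 and 180 deg cycling)."""
    return SteadyStateProtocol(
        spgr_tr=6.5, spgr_te=3.6, spgr_fas=(2.0, 3.0, 4.0, 6.0, 9.0, 13.0, 18.0),
        irspgr_tr=6.5, irspgr_te=3.2, irspgr_ti=450.0, irspgr_fa=5.0,
        bssfp_tr=5.8, bssfp_te=2.9,
        bssfp_fas=(7.0, 11.0, 15.0, 19.0, 24.0, 30.0, 47.0),
        phase_cycles=(0.0, 180.0),
    )


def cord_steady_state_protocol() -> SteadyStateProtocol:
    """Cord mcDESPOT session (SPGR / IRSPGR / bSSFP, 0 and 90 deg cycling)."""
    return SteadyStateProtocol(
        spgr_tr=5.5, spgr_te=2.7, spgr_fas=(2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 13.0, 18.0),
        irspgr_tr=5.5, irspgr_te=2.7, irspgr_ti=350.0, irspgr_fa=5.0,
        bssfp_tr=10.0, bssfp_te=5.0,
        bssfp_fas=(7.0, 14.0, 21.0, 28.0, 35.0, 42.0, 49.0),
        phase_cycles=(0.0, 90.0),
    )
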
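#!/usr/bin/env python
"""Multi-echo T2 arm: MWF recovery on the cord phantom.

Fits the stimulated-echo-corrected regularized-NNLS pipeline to a
noiseless cord acquisition (recovery audit against the seeded truth) and
to repeated noisy voxels at the default SNR (per-voxel precision audit).

Writes results/02_mwf_cord_rois.tsv and results/02_mwf_precision.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from mwimap.epg import epg_decay
from mwimap.phantom import ROI_GROUPS, make_phantom, simulate_grase
from mwimap.cohortstats import format_roi_table, roi_stats
from mwimap.reference import cord_grase_protocol
from mwimap.t2spectrum import fit_mwf_signal, fit_mwf_volume

SEED = 1
OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    spec = cord_grase_protocol()

    # noiseless whole-cord recovery
    truth, labels = make_phantom("cord", (32, 32, 8), seed=SEED)
    ds = simulate_grase(truth, spec, snr=np.inf)
    res = fit_mwf_volume(ds.echoes, spec, mask=truth.roi_mask("whole_cord"))
    fitted = roi_stats(res.mwf, labels, ROI_GROUPS["cord"])
    true_tab = roi_stats(truth.f_m_true, labels, ROI_GROUPS["cord"])
    tab = pd.DataFrame({
        "truth_pct": true_tab["mean_pct"].round(2),
        "fitted_pct": fitted["mean_pct"].round(2),
        "fitted_sd_pct": fitted["sd_pct"].round(2),
        "n_voxels": fitted["n_voxels"],
    })
    tab.to_csv(OUT / "02_mwf_cord_rois.tsv", sep="\t")
    print("noiseless cord ROI recovery (percent):")
    print(tab.to_string())

    # per-voxel precision vs SNR on a representative WM voxel
    rng = np.random.default_rng(SEED)
    rows = []
    sig = (0.22 * epg_decay(20.0, 450.0, 171.0, spec)
           + 0.78 * epg_decay(70.0, 1000.0, 171.0, spec))
    for snr in (60.0, 100.0, 400.0, 800.0):
        errs = []
        for _ in range(60):
            sigma = sig[0] / snr
            noisy = np.abs(sig + sigma * rng.standard_normal(spec.n_echoes)
                           + 1j * sigma * rng.standard_normal(spec.n_echoes))
            errs.append(fit_mwf_signal(noisy, spec).mwf - 0.22)
        rows.append({"snr": snr,
                     "median_abs_err_pct": round(100 * np.median(np.abs(errs)), 2),
                     "bias_pct": round(100 * np.mean(errs), 2)})
    prec = pd.DataFrame(rows)
    prec.to_csv(OUT / "02_mwf_precision.tsv", sep="\t", index=False)
    print("\nper-voxel MWF precision vs SNR (truth 22%):")
    print(prec.to_string(index=False))
    print("\nfinding: recovery is accurate noiselessly (discretization bias "
          "~0.5 pp); at the default acquisition SNR the short-T2 pool is "
          "only weakly identifiable per voxel, so single-voxel MWF carries "
          "large error until SNR reaches several hundred.")


if __name__ == "__main__":
    sys.exit(main())
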
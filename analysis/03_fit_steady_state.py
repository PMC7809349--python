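#!/usr/bin/env python
"""Steady-state arm: DESPOT1-HIFI exactness and mcDESPOT SRC behavior.

Audits the flip-angle correction (noiseless single-pool recovery plus the
SNR-100 volume RMSE) and then runs the stochastic-region-contraction
fitter on one noiseless two-pool voxel across seeds, reporting the point
estimates together with their retained-set dispersion — the fit
degeneracy is a finding, not a nuisance.

Writes results/03_despot1.tsv and results/03_src_seeds.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from mwimap.despot1 import fit_despot1_hifi, fit_despot1_volume
from mwimap.mcdespot import SrcBounds, src_fit
from mwimap.phantom import make_phantom, simulate_mcdespot
from mwimap.reference import brain_steady_state_protocol
from mwimap.ssmodels import PoolModel, bssfp_signal, irspgr_signal, spgr_signal

SEED = 1
OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    prot = brain_steady_state_protocol()

    rows = []
    for t1, kappa in [(700.0, 0.85), (900.0, 1.0), (1200.0, 1.1)]:
        p = PoolModel(f_myelin=0.0, t1_myelin=450, t2_myelin=20,
                      t1_free=t1, t2_free=80)
        spgr = spgr_signal(p, prot.spgr_tr, prot.spgr_fas, kappa=kappa)
        ir = irspgr_signal(p, prot.irspgr_tr, prot.irspgr_ti,
                           prot.irspgr_fa, kappa=kappa)
        r = fit_despot1_hifi(spgr, ir, prot)
        rows.append({"t1_true": t1, "kappa_true": kappa,
                     "t1_hat": round(r.t1, 2), "kappa_hat": round(r.kappa, 4)})
    truth, _ = make_phantom("brain", (16, 16, 16), seed=SEED)
    ds = simulate_mcdespot(truth, prot, snr=100, seed=SEED)
    _, _, kmap = fit_despot1_volume(ds, mask=truth.tissue_mask)
    rmse = float(np.sqrt(np.nanmean((kmap.data - truth.kappa)[truth.tissue_mask] ** 2)))
    d1 = pd.DataFrame(rows)
    d1.to_csv(OUT / "03_despot1.tsv", sep="\t", index=False)
    print("DESPOT1-HIFI noiseless recovery:")
    print(d1.to_string(index=False))
    print(f"volume kappa RMSE at SNR 100: {100*rmse:.2f}% of nominal")

    # SRC on one noiseless voxel, truth f_M = 0.15
    p = PoolModel(f_myelin=0.15, t1_myelin=450, t2_myelin=20, t1_free=1000,
                  t2_free=80, tau_myelin=150, delta_f=10.0)
    spgr = spgr_signal(p, prot.spgr_tr, prot.spgr_fas, kappa=1.0)
    bssfp = {pc: bssfp_signal(p, prot.bssfp_tr, prot.bssfp_fas, pc,
                              kappa=1.0, te=prot.bssfp_te)
             for pc in prot.phase_cycles}
    bounds = SrcBounds.default(prot, three_pool=False)
    rows = []
    for s in range(10):
        r = src_fit(spgr, bssfp, prot, kappa=1.0, bounds=bounds, seed=SEED + s)
        rows.append({
            "seed": SEED + s,
            "fm_hat": round(r.estimates["f_myelin"], 4),
            "fm_dispersion": round(r.dispersion["f_myelin"], 4),
            "tau_hat_ms": round(r.estimates["tau_myelin"], 1),
            "tau_dispersion_ms": round(r.dispersion["tau_myelin"], 1),
            "cost": r.cost,
        })
    src = pd.DataFrame(rows)
    src.to_csv(OUT / "03_src_seeds.tsv", sep="\t", index=False)
    print("\nSRC across seeds (noiseless voxel, truth f_M = 0.15):")
    print(src.to_string(index=False))
    print(f"mean f_M estimate: {src['fm_hat'].mean():.3f}")
    print("\nfinding: the flip-angle correction is essentially exact; the "
          "multi-pool steady-state fit is degenerate — near-equal fits "
          "across a wide f_M range leave the retained-set mean biased high "
          "with large dispersion, echoing the known instability of this "
          "estimator.")


if __name__ == "__main__":
    sys.exit(main())
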
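#!/usr/bin/env python
"""End-to-end lesion detection: cohort atlas, Z-score maps, CoV masking.

Simulates a healthy brain cohort plus one subject carrying a focal lesion
(50% myelin-fraction reduction), fits the MWF arm for every subject,
builds the mean/SD atlas from the healthy subjects, and Z-scores the
lesioned subject against it with the 0.75 coefficient-of-variation mask
and the Z <= -1.96 deficiency cut. Run twice: noiseless (method audit)
and at the default acquisition SNR (study condition).

Writes results/05_lesion_detection.tsv and a Z histogram per condition.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from mwimap.cohortstats import build_atlas, zscore_histogram, zscore_map
from mwimap.phantom import CohortSpec, LesionSpec, make_cohort
from mwimap.t2spectrum import fit_mwf_volume

SEED = 1
OUT = Path("results")


def run(snr, label):
    cohort = make_cohort(
        "brain", (16, 16, 16),
        CohortSpec(n_subjects=7, between_subject_cv=0.05, snr=snr, seed=SEED),
        lesions={6: LesionSpec(n_lesions=1, radius_vox=(2.5, 3.0),
                               f_m_reduction=0.5)},
    )
    maps = [fit_mwf_volume(s.grase.echoes, s.grase.spec,
                           mask=s.truth.tissue_mask).mwf for s in cohort]
    atlas = build_atlas(maps[:6])
    z = zscore_map(maps[6], atlas, cov_threshold=0.75, deficiency_cut=-1.96)
    lesion = cohort[6].truth.lesion_mask
    core = lesion.copy()
    idx = np.argwhere(lesion)
    d = np.linalg.norm(idx - idx.mean(axis=0), axis=1)
    core[tuple(idx[d > np.median(d)].T)] = False

    edges, counts = zscore_histogram(z, bin_width=0.5)
    if edges.size:
        pd.DataFrame({"bin_lo": edges[:-1], "count": counts}).to_csv(
            OUT / f"05_zhist_{label}.tsv", sep="\t", index=False)
    return {
        "condition": label,
        "snr": snr if np.isfinite(snr) else "inf",
        "lesion_core_voxels": int(core.sum()),
        "core_flagged_pct": round(100 * float(np.mean(z.deficient_mask[core])), 1),
        "whole_lesion_flagged_pct": round(100 * float(np.mean(z.deficient_mask[lesion])), 1),
        "cov_excluded_voxels": int(z.cov_excluded_mask.sum()),
        "defined_z_voxels": int(np.isfinite(z.z.data).sum()),
    }


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = [run(np.inf, "noiseless"), run(100.0, "snr100")]
    tab = pd.DataFrame(rows)
    tab.to_csv(OUT / "05_lesion_detection.tsv", sep="\t", index=False)
    print(tab.to_string(index=False))
    print("\nfinding: with precise per-voxel MWF (noiseless condition) the "
          "Z-score pipeline flags essentially the whole lesion core; at the "
          "default acquisition SNR the atlas coefficient of variation "
          "exceeds the 0.75 mask almost everywhere and detection collapses "
          "— per-voxel MWF precision, not the statistics, is the limiting "
          "factor.")


if __name__ == "__main__":
    sys.exit(main())
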
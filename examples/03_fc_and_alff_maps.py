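"""Per-subject voxel-wise measures: global FC and band-limited ALFF.

One subject's run is nuisance-regressed (6 motion parameters + 5
aCompCor components from WM/CSF), detrended, band-pass filtered, and
summarized as (i) the mean Fisher-z correlation of each voxel with the
rest of the brain and (ii) the mean square-root periodogram power in
the band.
"""

import numpy as np

from lffcouple.bands import FULL_BAND, SLOW4, SLOW5
from lffcouple.fluctuation_metrics import alff_map, global_fc_map
from lffcouple.preprocess import bandpass, preprocess_run
from lffcouple.synthetic_cohort import cohort_geometry, generate_cohort, small_spec

spec = small_spec(n_per_group=2, seed=3)
geom = cohort_geometry(spec)
records, runs, masks = generate_cohort(spec)
rec, run = records[0], runs[0]

prepared = preprocess_run(run, masks, motion=rec.motion)  # regress + detrend
for band in (FULL_BAND, SLOW5, SLOW4):
    fc = global_fc_map(bandpass(prepared, band), masks.brain, band)
    alff = alff_map(prepared, band, masks.brain)
    gm_fc = np.nanmean(fc.values[masks.gm])
    wm_fc = np.nanmean(fc.values[masks.wm])
    gm_alff = np.nanmean(alff.values[masks.gm])
    wm_alff = np.nanmean(alff.values[masks.wm])
    print(f"{band.name:>6} ({band.f_low}-{band.f_high} Hz): "
          f"GM FC-z {gm_fc:+.4f} vs WM {wm_fc:+.4f} | "
          f"GM ALFF {gm_alff:.3f} vs WM {wm_alff:.3f}")
print()
print("Grey matter shows positive global connectivity and higher fluctuation")
print("amplitude than white matter, whose shared physiological signal was")
print("removed by the aCompCor regression.")
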
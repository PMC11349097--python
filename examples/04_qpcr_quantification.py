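"""Aptamarker quantification from raw qPCR fluorescence.

Simulates duplicate-well amplification curves for three samples over the
eight-aptamarker panel with known efficiency and crossing cycle, then runs
the full quantification: baseline, Cq at 6x baseline, efficiency from the
log-linear region, run normalisation, replicate CV QC, RT = (1/E)^Cq and
per-sample RTp proportions.
"""

import numpy as np
import pandas as pd

from neomer import quantify_plate
from neomer.simulate import RTP_FEATURES, QpcrTruth, simulate_qpcr

rng = np.random.default_rng(5)
truths = []
for s in range(3):
    for apt in RTP_FEATURES:
        E = float(rng.uniform(1.8, 2.0))
        cq = float(rng.uniform(18, 24))
        for rep in range(2):
            truths.append(QpcrTruth(f"w{s}:{apt}:{rep}", f"S{s}", apt, "run1", E, cq))

curves = simulate_qpcr(truths, noise_sigma=0.01, seed=6)
rows = [{"run_id": c.run_id, "well_id": c.well_id, "sample_id": c.sample_id,
         "aptamarker": c.aptamarker_name, "cycle": int(cyc), "fluorescence": f}
        for c in curves for cyc, f in zip(c.cycles, c.fluorescence)]

wells, runs, rtp = quantify_plate(pd.DataFrame(rows))
print(f"{int(wells.qc_pass.sum())}/{len(wells)} wells passed QC")
print(f"run normalisation: mean Cq {runs.mean_Cq[0]:.2f} "
      f"(factor {runs.factor_Cq[0]:.3f}), mean E {runs.mean_E[0]:.3f}")

t0 = truths[0]
w0 = wells[wells.well_id == t0.well_id].iloc[0]
print(f"\nexample well {t0.well_id}: true Cq={t0.Cq:.2f} E={t0.E:.3f} -> "
      f"called Cq={w0.Cq:.2f} E={w0.E:.3f}")

print(f"\nRTp matrix ({rtp.shape[0]} samples x {rtp.shape[1]} aptamarkers), "
      f"row sums {rtp.sum(axis=1).round(9).tolist()}:")
print(rtp.round(3).to_string())
# Each row is one sample's proportional aptamarker abundance profile —
# the feature vector used for classification.
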
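"""Count labelled clock-neuron somata and quantify ROI intensity.

Generates synthetic hemisphere images (normally four PDF-positive somata;
a 'toxic' genotype loses some), counts somata automatically, tests the
4-vs-fewer contingency by chi-square, and demonstrates background-corrected
ROI intensity on a known blob.
"""

import numpy as np

from circatox import image_quant as iq, synthetic_data as sd

programmed = {"control": [4, 4, 4, 4, 4, 4, 3, 4], "toxic": [4, 3, 2, 3, 2, 4, 3, 2]}
detected, seed = {}, 100
for genotype, counts in programmed.items():
    det = []
    for c in counts:
        cfg = sd.SimulationConfig(seed=seed, image=sd.ImageParams(n_blobs=c))
        seed += 1
        img, _, _ = sd.gen_roi_image(cfg)
        n, _ = iq.count_somata(img)
        det.append(n)
    detected[genotype] = det
    print(f"{genotype:>8}: programmed {counts} -> detected {det}")

table = iq.count_complement(detected)
rep = iq.compare_counts(table)
print(f"\n4-vs-fewer table: {table.full} full, {table.fewer} fewer")
print(f"chi-square = {rep.statistic:.2f}, p = {rep.p_value:.4f}")

cfg = sd.SimulationConfig(seed=3, image=sd.ImageParams(n_blobs=1, bg_sd=3.0))
img, masks, _ = sd.gen_roi_image(cfg)
# move the very same ROI mask to a signal-free corner
ys, xs = np.nonzero(masks[0].mask)
bg = iq.RoiMask(np.roll(masks[0].mask, (10 - ys.min(), 10 - xs.min()), axis=(0, 1)))
res = iq.background_subtract(img, masks[0], bg)
print(
    f"\nROI intensity: signal {res.s_signal:.1f}, background {res.s_background:.1f}, "
    f"corrected {res.corrected:.1f} grey units"
)
print(
    "Exact soma-count recovery at this SNR reproduces the programmed "
    "contingency table; corrected intensity is independent of the camera's "
    "additive offset."
)
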
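"""Calibrate the DWI infarct threshold offset on labeled phantoms.

The infarct threshold is the DWI histogram peak plus a fixed offset.
This sweep segments infarcts at offsets 0..30 against ground-truth cores
over several phantoms and reports the mean Dice (SI) per offset - the
calibration curve behind the default offset of 19.
"""

from wmhseg import (PhantomSpec, apply_mask, generate_phantom,
                    normalize_to_range, peak_offset_sweep)

cases = []
for seed in range(3):
    ph = generate_phantom(PhantomSpec.with_infarct(seed=seed))
    brain = ph.truth["brain"]
    dwi_norm = normalize_to_range(apply_mask(ph.dwi, brain), brain)
    cases.append((dwi_norm, brain, ph.truth["infarct"]))

rows = peak_offset_sweep(cases, offsets=range(0, 31, 3))
print("offset  mean SI %  (SD)")
for off, mean_si, sd_si in rows:
    print(f"  +{off:<4d} {mean_si:8.2f}  ({sd_si:.2f})")

best = max(rows, key=lambda r: r[1])
print(f"best offset on these phantoms: +{best[0]} (SI {best[1]:.2f} %)")
# Small offsets flood the segmentation with normal tissue (low SI);
# large offsets erode the detected core. The plateau near the optimum is
# what makes a fixed offset transferable across hemispheres.
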
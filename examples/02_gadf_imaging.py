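"""Turn one segmented beat into a stacked GADF tensor.

Each lead is min-max rescaled to [0, 1], block-averaged (PAA) to the image
size, mapped to polar angles phi = arccos(x), and imaged as the difference
field G[i, j] = sin(phi_i - phi_j); the per-lead images stack into an
(M', M', C) tensor.
"""

import numpy as np

from ecgtensor import DEFAULT_BEAT, MorphLabel, build_tensor, synthesize_stream
from ecgtensor.io import ECGRecord, detect_r_peaks, segment_cycles

stream = synthesize_stream(DEFAULT_BEAT, [MorphLabel.NORMAL] * 8, seed=0)
record = ECGRecord("demo", stream.sample_rate,
                   [f"lead_{i+1}" for i in range(stream.n_leads)], stream.samples)
peaks = detect_r_peaks(record)
cycles = segment_cycles(record, peaks, out_len=128)
tensor = build_tensor(cycles[0], image_size=32)

print(f"detected {len(peaks)} beats; tensor shape: {tensor.shape}")
print(f"pixel range: [{tensor.min():.3f}, {tensor.max():.3f}]  (bounded by ±1)")
print(f"antisymmetry error: {np.max(np.abs(tensor[:, :, 0] + tensor[:, :, 0].T)):.2e}")
# Every slice is an antisymmetric image of pairwise temporal correlation;
# the zero diagonal is the beat compared with itself.
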
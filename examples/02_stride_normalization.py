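"""Normalize burst times to the stride cycle and summarize timing.

Expresses each detected burst's onset/offset as relative stride time in
[0, 1) (stance mapped to [0, 0.71), swing to [0.71, 1)), then aggregates
mean +- SE across strides — the summary one would tabulate per muscle.
"""

import pandas as pd

import phyloemg as pe

strides = pe.gen_stride_events(8, stance_s=0.5, swing_s=0.2, jitter_frac=0.05, seed=4, start_s=0.5)
# plant a pectoralis-like burst: onset in late swing, offset at mid-stance
bursts = []
for i in range(1, strides.n_strides):
    td, lo, nxt = strides.cycle(i)
    prev_td, prev_lo, _ = strides.cycle(i - 1)
    onset = prev_lo + 0.7 * (td - prev_lo)  # late swing of the previous cycle
    offset = td + 0.75 * (lo - td)  # mid-stance
    bursts.append(pe.BurstInterval("PEC_sim_ch1", onset, offset, mean_amplitude=20.0))

normed = pe.normalize_bursts(bursts, strides, stance_fraction=0.71)
frame = pd.DataFrame(
    {
        "muscle": "PEC",
        "burst_index": 1,
        "stride": [b.stride_index for b in normed],
        "onset_cycle": [b.onset_cycle for b in normed],
        "offset_cycle": [b.offset_cycle for b in normed],
        "duration": [pe.normalized_duration(b) for b in normed],
    }
)
print(frame.round(3).to_string(index=False))
summary = pe.aggregate_timings(frame)
print(summary.round(4).to_string(index=False))
print("Onsets near 1 mean the burst starts in the previous cycle's swing;")
print("duration is measured across the wrap (offset - onset, mod 1).")
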
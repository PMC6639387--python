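"""Extract the three slowing biomarkers from a filtered recording.

Applies the amplifier filter cascade (band-stop 55-65 Hz, high-pass 2.6 Hz,
low-pass 43 Hz), screens for voltage artifacts, and computes MDF, PF and
ATR per channel and channel-averaged.
"""

from eegslow import (
    EEGSimParams,
    apply_device_filters,
    extract_biomarkers,
    simulate_eeg,
)

rec = simulate_eeg(EEGSimParams(duration_s=300.0, peak_freq=8.8,
                                blink_rate=2.0, seed=3))
rec = apply_device_filters(rec)
bm = extract_biomarkers(rec)

print("channel-averaged biomarkers (lower MDF/PF/ATR = more EEG slowing):")
print(f"  MDF {bm.mdf:.2f} Hz   PF {bm.pf:.2f} Hz   ATR {bm.atr:.2f}")
for ch, vals in bm.per_channel.items():
    print(f"  {ch}: MDF {vals['mdf']:.2f}  PF {vals['pf']:.2f}  "
          f"ATR {vals['atr']:.2f}")
for th, res in bm.screens.items():
    frac = max(res.fraction.values())
    print(f"  screen {th} uV: worst-channel fraction {frac:.4f} "
          f"({'pass' if res.passed else 'FAIL'})")
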
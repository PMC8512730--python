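"""Sweep the solenoid pitch: CIDS tracks fiber compaction.

Pitch 0 is a planar nucleosome ring (achiral, zero CIDS); increasing pitch
unwinds the fiber and strengthens the differential circular scattering,
while the extinction efficiency barely moves -- total intensity sees size,
CIDS sees chirality.
"""

import chiroscat as cs
from chiroscat import experiments as ex

cfg = ex.SweepConfig(
    sweep_kind="pitch",
    values=[0.0, 5.5, 11.0, 16.5, 22.0],
    dipoles_per_longest=16,
)
result = ex.run_sweep(cfg)
assert result.ok, result.failures

print("pitch [nm]   max|CIDS|     Q_ext       N dipoles")
for _, row in result.per_value().iterrows():
    print(f"  {float(row['value']):5.1f}     {row['max_abs_cids']:.4e}   {row['Q_ext']:.4e}   {int(row['n_dipoles']):5d}")
print("\nCIDS is zero for the pitch-0 ring and grows monotonically with pitch;")
print("Q_ext varies only weakly across the same sweep.")
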
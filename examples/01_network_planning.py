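"""Plan an optode-module network: channels and achievable sampling rate.

Two hexagonal modules 40 mm apart give 2x2 = 4 optical channels: two
short-separation (SS, 7.5 mm on-board) channels sampling the scalp only and
two long-separation (LS, 40 mm) channels reaching the cortex.  The shared
measurement cycle bounds the per-channel sampling frequency.
"""

import nirstwin as nt

network = nt.OptodeNetwork.from_positions([(0.0, 0.0), (40.0, 0.0)])

print(f"{'channel':<8}{'kind':<6}{'SDS (mm)':>9}")
for ch in nt.enumerate_channels(network):
    print(f"{ch.label:<8}{ch.kind:<6}{ch.sds:>9.1f}")

rates = nt.effective_sampling_rate(network)
print(f"\nper-channel sampling: formula {rates['formula_hz']:.2f} Hz, "
      f"cycle bound {rates['cycle_bound_hz']:.2f} Hz, "
      f"effective {rates['effective_hz']:.2f} Hz")

print(f"10-module configuration: {len(nt.enumerate_channels(nt.OptodeNetwork.from_positions([(30.0 * k, 0.0) for k in range(10)])))} channels "
      f"at {nt.sampling_frequency(10, 10):.2f} Hz each")
print("\nEvery module takes a turn as source while all modules (itself "
      "included) detect; communication adds 0.6 ms per module read out.")
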
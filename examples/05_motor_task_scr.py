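"""Motor-task pipeline with short-channel regression.

A 20-s task / 20-s rest block design repeated 10 times: the long channel
(40 mm) sees systemic scalp oscillations plus the cerebral hemodynamic
response, the short channel (7.5 mm) sees the scalp only.  After MBLL
reconstruction, 0.01-0.5-Hz zero-phase band-pass, sliding-window (120 s)
short-channel regression, and block averaging, the recovered O2Hb response
is compared with the generator's ground truth.
"""

import nirstwin as nt
from nirstwin.processing import FilterSpec

fs, seed = 25.0, 1
spec = nt.MotorBlockSpec()
network = nt.OptodeNetwork.from_positions([(0.0, 0.0), (40.0, 0.0)])
extra = nt.systemic_oscillations(spec, fs=fs, seed=seed)
cerebral = nt.motor_task_response(spec, fs=fs)
rec = nt.simulate_recording(
    network, extra, cerebral, noise=nt.NoiseConfig.calibrated(), seed=seed
)

conc = {}
for label in ("S0D1", "S1D1"):
    i = rec.channel_index(label)
    ch = rec.channels[i]
    da = nt.delta_attenuation(rec.intensity[i], rec.backlight[i], rec.wavelengths)
    conc[label] = nt.reconstruct(da, nt.ExtinctionSystem.default(ch.sds), 3)

bpf = FilterSpec.motor_bandpass()
f_ls = nt.zero_phase_filter(conc["S0D1"], bpf, fs)
f_ss = nt.zero_phase_filter(conc["S1D1"], bpf, fs)
corrected = nt.short_channel_regression(f_ls[:2], f_ss[:2], fs, window_s=120.0)

epochs = nt.block_average(corrected, spec.onsets_s, fs)
truth = nt.block_average(cerebral.as_matrix()[:2], spec.onsets_s, fs)

rec_o2hb = epochs.mean[0].max()
true_o2hb = truth.mean[0].max()
print(f"trials averaged:              {epochs.n_trials}")
print(f"recovered O2Hb peak:          {rec_o2hb:+.3f} uM "
      f"(+- {epochs.sem[0].max():.3f} SE)")
print(f"ground-truth cerebral peak:   {true_o2hb:+.3f} uM")
print(f"recovery error:               {abs(rec_o2hb/true_o2hb - 1)*100:.1f} %")
print(f"recovered HHb trough:         {epochs.mean[1].min():+.3f} uM")
print("\nThe short-channel regression removes the scalp oscillations that "
      "dominate the raw long-channel signal, leaving the task-locked "
      "cerebral response.")
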
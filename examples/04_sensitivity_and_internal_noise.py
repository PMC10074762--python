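"""RMS sensitivity and agreement as a function of internal noise.

RMS of the kernel indexes how strongly the observer weights pitch;
agreement (share of choices matching the kernel's own prediction)
indexes internal noise: noisier observers agree less with themselves
and their kernels carry less energy.
"""

import numpy as np

import revpitch as rp

cfg = rp.speech_config()
template = rp.make_template("cubic", 8)

print(" sigma_int   RMS (cents)   agreement")
for sigma in (0.5, 2.0, 4.0, 6.0):
    rng = np.random.default_rng(40 + int(10 * sigma))
    pool = rp.build_stimulus_pool(cfg, rng)
    pairs = rp.pair_trials(pool, rng)
    obs = rp.ObserverSpec("demo", "sim", template, internal_noise_ratio=sigma)
    session = rp.simulate_session(obs, pairs, cfg, rng=rng)
    kernel = rp.estimate_kernel(session)
    agr, n_scored = rp.agreement(session, kernel)
    print(f"   {sigma:4.1f}     {rp.kernel_rms(kernel):8.2f}     "
          f"{agr:.3f}  ({n_scored} trials scored)")
# Both columns fall together as internal noise rises - the same positive
# RMS-agreement coupling observed in human reverse-correlation cohorts.
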
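"""Render contour stimuli to audio and verify the pitch with the F0 oracle.

The carrier is a harmonic complex (fundamental + seven odd harmonics,
sine phase).  Rendering is for validation and demos; the analysis
pipeline itself works on breakpoint shift vectors.
"""

import numpy as np

import revpitch as rp

tone_cfg = rp.complex_tone_config()
flat = rp.ContourStimulus("flat", np.zeros(8), "complex_tone")
wav = rp.render_harmonic_tone(flat, tone_cfg)
print(f"complex tone: {wav.duration_ms:.0f} ms, "
      f"estimated F0 = {rp.estimate_f0(wav):.2f} Hz (nominal 210)")

mel_cfg = rp.melody_config()
proto = rp.ContourStimulus("proto", rp.PROTOTYPE_MELODY, "melody")
wavm = rp.render_melody(proto, mel_cfg)
print(f"melody: {wavm.duration_ms:.0f} ms, base F0 nominal 260 Hz")
note_dur = mel_cfg.duration_s / 3
for k in range(3):
    mid = (k + 0.5) * note_dur
    f0 = rp.estimate_f0(wavm, frame=(mid - 0.1, mid + 0.1))
    semitones = 12 * np.log2(f0 / 260.0)
    print(f"  note {k + 1}: F0 = {f0:6.2f} Hz  ({semitones:+.2f} semitones)")
# The prototype contour [0, -500, 0] cents drops note 2 by five semitones
# and returns for note 3, which the per-note F0 estimates recover.
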
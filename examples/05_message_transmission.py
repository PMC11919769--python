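"""Light-to-ionic messaging: encode, transmit through pores, and decode.

A ternary pixel image and a Morse text are encoded as 20 s irradiation bits
(0 -> 455 nm, 1 -> 365 nm, 2 -> mixed 365+455 nm).  The pore ensemble
converts the light sequence into a three-level current pattern; the decoder
averages the settled half of each bit and quantizes against the
model-predicted photostationary levels (the pre-determined key).
"""

import numpy as np

import photopore as pp

schedule = pp.SymbolSchedule()  # 20 s/bit
model = pp.EnsembleModel.with_sampled_pores(200, seed=8)

levels = pp.predicted_symbol_levels(model, schedule)
print("symbol -> equilibrium level (pA):")
for s, lv in sorted(levels.items()):
    print(f"  {s}: {lv:8.1f}")

pixels = np.array([[2, 1, 2],
                   [1, 0, 1],
                   [2, 1, 2]])
image = pp.Message(pixels, "ternary")
trace = pp.transmit(image, model, schedule, seed=21, sample_rate=200)
trace = pp.bessel_lowpass(trace, 20.0)
decoded = pp.decode(trace, schedule, levels, "ternary", shape=pixels.shape)
print(f"\nsent pixels:\n{pixels}")
print(f"decoded pixels:\n{decoded.payload}")
print(f"bit error rate: {pp.bit_error_rate(image, decoded):.3f} "
      f"over {len(image.symbols())} bits")

text = pp.Message("SOS", "morse3")
print(f"\n'SOS' as Morse: {pp.text_to_morse('SOS')}")
tr2 = pp.transmit(text, model, schedule, seed=22, sample_rate=200)
out = pp.decode(pp.bessel_lowpass(tr2, 20.0), schedule, levels, "morse3")
print(f"decoded text: {out.payload!r} "
      f"({tr2.duration_s:.0f} s of irradiation)")
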
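"""Compare conventional and short-template CLEAN on overlapping echoes.

Two echoes 10 bins apart (closer than the 24-bin pulse) overlap; the
full-template correlation is distorted by the overlap while the
front-quarter short template still pins the nearest echo's bin exactly.
"""

import numpy as np

from uwbspeech import (
    conventional_clean,
    make_pulse_template,
    make_short_template,
    short_template_clean,
)

template = make_pulse_template(24)
short = make_short_template(template, 0.25)

y = np.zeros(256)
y[30:54] += 5.0 * template.samples            # lips at bin 30
y[40:64] += 2.5 * template.samples[:24]       # jaw/face echo at bin 40, overlapping

det = short_template_clean(y, short)
print(f"short-template CLEAN: bin {det.bin}, amplitude {det.amplitude:.3f} "
      "(true nearest echo: bin 30, amplitude 5)")

dets = conventional_clean(y, template, t_stop=2.0)
print("conventional CLEAN detections (bin, amplitude):",
      [(d.bin, round(d.amplitude, 3)) for d in dets])
print("-> the overlap perturbs the conventional amplitudes; the nearest-echo")
print("   feature from the short template stays exact, which is why the")
print("   recognizer is fed from the short-template clean map.")
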
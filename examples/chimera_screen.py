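"""Flag a PCR chimera among denoised sequences.

A chimera concatenates the prefix of one real template with the suffix of
another during PCR.  Here one is constructed from two abundant parents and
planted at low abundance; the detector must identify both the event and the
crossover column, without flagging the real parents.
"""

import numpy as np

from subotu import DenoiseResult, detect_chimeras

rng = np.random.default_rng(0)
L = 80
p1 = "".join(rng.choice(list("ACGT"), L))
p2 = "".join(rng.choice(list("ACGT"), L))
crossover = 37
chimera = p1[:crossover] + p2[crossover:]

result = DenoiseResult(retained=[(p1, 500), (p2, 420), (chimera, 35)])
for v in detect_chimeras(result):
    label = "CHIMERA" if v.is_chimera else "ok"
    extra = f" crossover={v.crossover}" if v.is_chimera else ""
    print(f"{v.sequence[:20]}...  {label}{extra}")
# the planted sequence is flagged with a crossover at (or left of) column 37
# -- any column between the last parent difference before 37 and the first
# after it reconstructs the same chimera; the parents themselves are not
# flagged because no model explains them at the required abundance skew.
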
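"""Quintic smoothstep switching used by all short-range terms.

s(x) = 1 - 10 x^3 + 15 x^4 - 6 x^5 on x = (r - r_in)/(r_out - r_in),
clamped to 1 below r_in and 0 above r_out; C^2 at both ends.
"""

import numpy as np


def switch(r, r_in: float, r_out: float):
    """Return (s, ds/dr) for scalar or array ``r``."""
    r = np.asarray(r, dtype=float)
    x = np.clip((r - r_in) / (r_out - r_in), 0.0, 1.0)
    s = 1.0 - x**3 * (10.0 - 15.0 * x + 6.0 * x**2)
    ds = -30.0 * x**2 * (1.0 - x) ** 2 / (r_out - r_in)
    return s, ds
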
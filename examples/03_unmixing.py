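"""Fully constrained unmixing of a bottom spectrum.

Mixes the three library endmembers with known fractions, unmixes the
result, and shows the recovered abundances and spectral residual.
"""

import numpy as np

import shallowsea as ss

lib = ss.default_library()
truth = np.array([0.2, 0.5, 0.3])
spectrum = ss.mix_albedo(truth, lib)

ab, resid = ss.fclu_unmix(spectrum, lib)
print("endmembers:", ", ".join(lib.names))
print("true fractions:     ", np.round(truth, 4))
print("recovered fractions:", np.round(ab, 4), " residual %.2e" % resid)

noisy = np.clip(spectrum + np.random.default_rng(0).normal(0, 0.01, spectrum.size),
                0, 1)
ab_n, resid_n = ss.fclu_unmix(noisy, lib)
print("with 0.01 noise:    ", np.round(ab_n, 4), " residual %.2e" % resid_n)
print("\nFractions stay on the unit simplex by construction; the residual is")
print("the RMS spectral misfit left after the constrained least-squares fit.")
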
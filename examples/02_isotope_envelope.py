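"""Isotope envelopes: what the precursor looks like in a SIM scan.

Computes the natural-abundance isotopologue envelope of the FdUMP anion and
scores a slightly perturbed "measured" copy against it — the check used to
validate an identification.
"""

import numpy as np

from tsimquant import builtin_panel, isotope_pattern, isotope_pattern_score

fdump = next(t for t in builtin_panel() if t.name == "FdUMP")
pattern = isotope_pattern(fdump.formula, adduct="[M-H]-")

print("FdUMP [M-H]- isotope envelope (truncated at 0.1% of base peak):")
for mz, abundance in pattern.peaks:
    print(f"  {mz:10.4f}  {abundance:8.5f}")
print(f"  total abundance kept: {pattern.total_abundance():.5f}")

rng = np.random.default_rng(0)
measured = [
    (mz * (1 + rng.normal(0, 1e-6)), ab * (1 + rng.normal(0, 0.02)))
    for mz, ab in pattern.peaks
]
score = isotope_pattern_score(measured, pattern, mz_tol_ppm=5)
print(f"\nisotope agreement score at 1 ppm mass error, 2% intensity error: "
      f"{score:.1f}/100")
# 100 means a perfect envelope match; the score drops to 0 if the
# monoisotopic peak is missing from the measurement.
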
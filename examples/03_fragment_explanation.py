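"""Fragment explanation: each fingerprint fragment as a piece of its precursor.

Every observed fragment m/z is searched against all elemental sub-multisets
of the deprotonated precursor composition; a hit within 10 ppm explains the
fragment and contributes its signed mass deviation to the validation score.
"""

from tsimquant import builtin_panel, validate_fragments

fdump = next(t for t in builtin_panel() if t.name == "FdUMP")
score = validate_fragments(fdump, list(fdump.fragments), tol_ppm=10)

print(f"FdUMP fragment fingerprint ({score.explained}/{score.total} explained, "
      f"score {score.fragment_score:.0f}/100):")
for frag, formula in score.explanations.items():
    print(f"  {frag:9.4f}  ->  [{formula}]-")
print(f"median mass deviation: {score.median_ppm_deviation:+.2f} ppm "
      f"(gate: |median| <= 5 ppm -> {'pass' if score.passes else 'fail'})")
# 96.969 resolves to dihydrogen phosphate and 78.959 to metaphosphate -
# the classic nucleotide backbone fragments; 129.01 is the fluorouracil
# anion released from the nucleoside.
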
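"""A full comparative study: parental vs 5-FU-resistant cells.

Simulates the complete design (both groups, treated and untreated controls,
lysate and media, calibrants, per-batch QC references), runs the whole
pipeline, and prints the group-comparison table. The resistant group is
configured with the fluorinated metabolites FdUMP/FURD/FdURD at 0.4x the
parental level; 5-FU and the endogenous nucleotides are unchanged; FUTP and
FdUTP are absent.
"""

from tsimquant import builtin_panel, default_study_design, process_study, simulate_study

design = default_study_design(replicates=5)
study = simulate_study(design, seed=2024)
n_test = (study.sample_sheet["role"] == "test").sum()
print(f"simulated {len(study.runs)} runs ({n_test} test samples)")

report = process_study(study.runs, study.sample_sheet, builtin_panel())

for curve in report.calibrations.values():
    print(f"calibration {curve.compound}: slope {curve.slope:,.0f}, "
          f"R^2 {curve.r_squared:.5f}, LOD {curve.lod:.3g} ng/uL")

columns = ["compound", "matrix", "status", "fold_change", "p_value", "significant"]
print("\ngroup comparison (fold change = resistant / parental):")
print(report.summary[columns].to_string(index=False))
# Expected pattern: FdUMP and FURD significantly reduced in both matrices,
# FdURD reduced in media (absent from lysate), 5-FU/dUMP/TMP unchanged,
# FUTP/FdUTP below detection everywhere.
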
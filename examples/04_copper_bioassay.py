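"""Analyse a simulated 72-h copper bioassay: %I per concentration + t-test.

A test strain (EC50 = 0.32 mg/L) against a more sensitive reference
(EC50 = 0.1 mg/L); percent inhibition rises with dose, the top dose shows
no growth, and the tolerance difference at 0.32 mg/L is tested with a
pooled-variance Student's t-test.
"""

from algascreen.bioassay import analyze_panel, compare_to_reference
from algascreen.synthetic import DoseSimConfig, simulate_dose_response

test_panel, _ = simulate_dose_response(
    DoseSimConfig(mu0=1.0, ec50=0.32, hill=2.0, noise_cv=0.05, seed=3, strain_id="test")
)
ref_panel, _ = simulate_dose_response(
    DoseSimConfig(mu0=1.0, ec50=0.10, hill=2.0, noise_cv=0.05, seed=4, strain_id="reference")
)

test = analyze_panel(test_panel)
ref = analyze_panel(ref_panel)

print("test strain, percent inhibition by copper concentration:")
for _, row in test.per_concentration.iterrows():
    flag = "  (no growth)" if row["no_growth"] else ""
    print(f"  {row['concentration_mg_L']:>5.2f} mg/L: %I = {row['percent_inhibition']:6.1f}{flag}")

t, p = compare_to_reference(test.rates_at(0.32), ref.rates_at(0.32))
print(f"\ntolerance at 0.32 mg/L, test vs reference: t = {t:.2f}, p = {p:.4f}")
print("p < 0.05 means the test strain grows significantly faster than the"
      " reference at that copper level.")
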
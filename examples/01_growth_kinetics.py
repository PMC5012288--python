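"""Fit specific growth rates and generation times from simulated OD curves.

Three cultures with known intrinsic rates are sampled every 24 h for seven
days with 5% multiplicative noise; the exponential-window fit should
recover each rate to within a few percent.
"""

from algascreen.growth import fit_exponential_window
from algascreen.synthetic import GrowthSimConfig, simulate_growth_curve

for i, mu_true in enumerate((0.4, 0.7, 1.2)):
    cfg = GrowthSimConfig(
        mu_true=mu_true, noise_cv=0.05, seed=i, strain_id=f"strain{i + 1}"
    )
    curve, truth = simulate_growth_curve(cfg)
    fit = fit_exponential_window(curve)
    print(
        f"{curve.strain_id}: true mu = {mu_true:.2f}/d, fitted mu = {fit.mu:.3f}/d, "
        f"generation time = {fit.generation_time_h:.1f} h, "
        f"window = points {fit.window[0]}..{fit.window[1] - 1}, r^2 = {fit.r_squared:.4f}"
    )

print(
    "\nmu is the slope of ln(OD) over the best <= 3-day window; generation time "
    "is 24 ln2 / mu. A strain with mu >= 1.0/d doubles in under ~16.6 h."
)
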
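"""Compute the six biodiesel quality indices for two contrasting FAME profiles.

An oleate-dominated profile (good ignition quality, low cold-flow risk)
versus a heavily polyunsaturated one (high iodine value, fails the ASTM
screen).
"""

from algascreen.fame import FameProfile
from algascreen.indices import astm_screen, compute_indices

profiles = [
    FameProfile("oleate_rich", {"C16:0": 15.0, "C18:1": 80.0, "C18:2": 5.0}),
    FameProfile("pufa_rich", {"C16:0": 20.0, "C16:4(n-3)": 55.0, "C18:2": 25.0}),
]

for prof in profiles:
    idx = compute_indices(prof)
    screen = astm_screen(idx)
    print(f"{prof.strain_id}:")
    print(f"  CN = {idx.cn:.1f}  (ASTM needs >= 47: {'pass' if screen.cn_pass else 'FAIL'})")
    print(f"  IV = {idx.iv:.1f}  (ASTM needs <= 120: {'pass' if screen.iv_pass else 'FAIL'})")
    print(f"  DU = {idx.du:.1f} wt%, LCSF = {idx.lcsf:.2f} wt%")
    print(f"  SV = {idx.sv:.1f} mg KOH/g, CFPP = {idx.cfpp:.1f} degC "
          f"(reported {idx.cfpp_reported} degC)")
    print(f"  ASTM screen overall: {'PASS' if screen.overall_pass else 'FAIL'}\n")

print(
    "Unsaturation trades ignition quality (CN down, IV up) against cold-flow "
    "behaviour (LCSF and CFPP down): feedstock screening balances the two."
)
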
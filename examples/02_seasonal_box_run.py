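"""One seasonal box-model run with adaptive trait dynamics.

Integrates the eight-tracer NPZD-Fe box with the moment-closure size
distribution for three years under high-amplitude seasonal nutrient
supply, with trait diffusion sustaining diversity, and prints the
final-year seasonal cycle of the community state.
"""

import numpy as np

import sizebef as sb

state = sb.BoxState.from_moments(sb.TraitState(P=0.25, mean_l=2.0, var_v=0.05))
run = sb.integrate(
    state,
    sb.Forcing(),  # high-amplitude seasonal supply by default
    dc=sb.DiversityControls(u=0.05),
    years=3,
)

final = run.final_year()
month = np.arange(365) // 30
print("final-year monthly means:")
print("month    N      P    mean_l  var_v    mu     NPP")
for mo in range(12):
    sel = month == mo
    row = [final.data[k][sel].mean() for k in ("N", "P", "mean_l", "var_v", "mu", "NPP")]
    print(f"{mo + 1:3d}  {row[0]:6.2f} {row[1]:6.2f} {row[2]:7.2f} {row[3]:6.3f} "
          f"{row[4]:6.3f} {row[5]:7.1f}")

ts = sb.TraitState(
    P=final.data["P"].mean(),
    mean_l=final.data["mean_l"].mean(),
    var_v=final.data["var_v"].mean(),
)
print(f"\nannual NPP          : {final.data['NPP'].mean():7.1f} mg C m^-3 d^-1")
print(f"size diversity      : {sb.size_diversity(ts):7.3f} (ln um^3)^2")
print(f"picophyto (< 2 um)  : {sb.pico_fraction(ts):7.2%} of biomass")
print(f"sub-steps were taken automatically during stiff bloom drawdowns; "
      f"clamp events: {run.metadata['clamp_events']}")
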
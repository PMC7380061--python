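"""Why does sustaining diversity change productivity?  Two attributions.

Integrates a paired low/high trait-diffusion box run, then

* splits the NPP difference per unit coefficient into its six chain-rule
  routes (through biomass, growth rate, N:C quota, carbon-growth
  curvature and trait variance), and
* expands the final-year mean growth rate around the seasonal means,
  attributing it to seasonal variances and trait-environment covariances.
"""

import sizebef as sb

state = sb.BoxState.from_moments(sb.TraitState(P=0.25, mean_l=2.0, var_v=0.05))
runs = {}
for u in (0.0, 0.1):
    runs[u] = sb.integrate(
        state, sb.Forcing(), dc=sb.DiversityControls(u=u), years=5
    )

res = sb.chain_decomposition(runs[0.0], runs[0.1], delta_u=0.1)
print("chain-rule attribution of Delta NPP / Delta u (final units summed over 5 y):")
for name in ("term_mu", "term_QN", "term_P", "term_curv", "term_P_curv", "term_v"):
    print(f"  {name:12s} {getattr(res, name):12.1f}")
print(f"  {'sum':12s} {res.terms_sum:12.1f}")
print(f"  {'exact total':12s} {res.total:12.1f}   (residual {res.residual:.1f})")
print("A positive growth-rate route offset by negative quota and variance "
      "routes is the stoichiometry story: diversity raises mu but also Q_N.")

tay = sb.taylor_decomposition(runs[0.1], window=365)
print("\nsecond-order seasonal expansion of the final-year mean growth rate:")
print(f"  mu at seasonal means : {tay.base:8.4f} d^-1")
print(f"  var(mean size) term  : {tay.var_l:8.4f}")
print(f"  var(N) term          : {tay.var_N:8.4f}")
print(f"  var(I) term          : {tay.var_I:8.4f}")
print(f"  cov(size, N) term    : {tay.cov_lN:8.4f}")
print(f"  cov(size, I) term    : {tay.cov_lI:8.4f}")
print(f"  cov(I, N) term       : {tay.cov_IN:8.4f}")
print(f"  reconstructed mean   : {tay.terms_sum:8.4f}  "
      f"(true mean {tay.mu_bar:.4f}, error {tay.reconstruction_error:+.4f})")
print("The covariance between mean size and nutrient is the route by which "
      "diversity can raise productivity in a variable environment.  Under "
      "this high-amplitude forcing the truncated third-and-higher orders "
      "are visible as the reconstruction error; the expansion tightens as "
      "the seasonal amplitude shrinks.")
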
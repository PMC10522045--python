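"""Interpret sign-method coefficients as odds ratios and probabilistic indexes.

Uses the coefficient values from a published colorectal-cancer case study
(the genus Peptostreptococcus tested against a 4-taxon reference frame) to
show the two effect-size scales the methods report.
"""

from signda import or_from_beta, percent_lower_odds, pi_from_beta

beta_marg_s = -3.135   # marginal S-sign log-odds-ratio
beta_cond_s = -2.841   # conditional (given library size, gender, FIT)
beta_marg_r = 0.511    # marginal R-sign PIM coefficient
beta_cond_r = 0.433    # conditional R-sign PIM coefficient

print(f"marginal OR   exp({beta_marg_s}) = {or_from_beta(beta_marg_s)}")
print(f"conditional OR exp({beta_cond_s}) = {or_from_beta(beta_cond_s)}")
print(f"  -> the odds of the taxon sitting below its adjusted reference are "
      f"{percent_lower_odds(beta_marg_s):.0f}% lower in cases than controls,")
print("     i.e. the taxon is *more* abundant in cases, relative to the RF.")
print(f"marginal PI   expit({beta_marg_r}) = {pi_from_beta(beta_marg_r)}")
print(f"conditional PI expit({beta_cond_r}) = {pi_from_beta(beta_cond_r, 2)}")
print("  -> a case has a ~62% probability of carrying a higher relative "
      "abundance than a control.")
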
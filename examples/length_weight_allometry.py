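"""Fit W = a L^b and test whether growth is isometric (b = 3).

b = 3 means weight scales with the cube of length (shape is preserved
through ontogeny); b below 3 means fish get proportionally slimmer as
they grow.
"""

import dynapool as dp

catch = dp.simulate_population(dp.SyntheticConfig(n_fish=200, seed=7))
fit = dp.fit_power_law(catch)
iso = dp.isometry_t_test(fit, catch)
sexes = dp.sex_slope_test(catch)

print(f"W = {fit.a:.3e} * L^{fit.b:.4f}   (r^2 = {fit.r_squared:.4f}, n = {fit.n})")
print(f"95% CI for b: [{fit.b_interval.lower:.4f}, {fit.b_interval.upper:.4f}]")
print(f"isometry t-test: t = {iso.t_statistic:.3f}, df = {iso.df}, "
      f"p = {iso.two_sided_p:.3f} -> {iso.conclusion}")
print(f"sex comparison (slope homogeneity): F = {sexes.f_statistic:.3f}, "
      f"p = {sexes.p_value:.3f}")
print()
print("The simulated truth (b = 2.94) really is below 3, and at n = 200")
print("the t-test detects that mild negative allometry; a survey of ~50")
print("fish would usually not.  The non-significant F justifies pooling")
print("the sexes, which share one relationship here by construction.")
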
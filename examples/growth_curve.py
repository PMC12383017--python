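"""Fit the von Bertalanffy growth curve and derive life-history ages.

The inflection age t_i is where the weight growth *rate* peaks; the
critical age t_c is where an unfished cohort's biomass peaks -- both are
classic harvest-timing references.  phi = log10(k) + 2 log10(L_inf)
standardises growth rate by asymptotic size.
"""

import dynapool as dp

catch = dp.simulate_population(dp.SyntheticConfig(n_fish=300, seed=3))
lw = dp.fit_power_law(catch)
p = dp.fit_vbgf(catch.ages, catch.lengths)
M = dp.pauly_natural_mortality(p.L_inf.value, p.k.value, T=11.0)
derived = dp.derive_growth(p, lw, M)

print(f"L_inf = {p.L_inf.value:.1f} mm  [{p.L_inf.lower:.1f}, {p.L_inf.upper:.1f}]")
print(f"k     = {p.k.value:.4f} /yr  [{p.k.lower:.4f}, {p.k.upper:.4f}]")
print(f"t0    = {p.t0.value:.3f} yr   [{p.t0.lower:.3f}, {p.t0.upper:.3f}]")
print(f"W_inf = {derived.W_inf:.0f} g")
print(f"inflection age t_i = {derived.t_inflection:.2f} yr "
      f"(length {dp.length_at_age(p, derived.t_inflection):.0f} mm)")
print(f"critical age  t_c = {derived.t_critical:.2f} yr "
      f"(length {dp.length_at_age(p, derived.t_critical):.0f} mm)")
print(f"growth performance phi = {derived.phi:.2f}")
print()
print("k near 0.1/yr marks a slow-growing stock: it rebuilds slowly")
print("after depletion, so size limits matter more than effort alone.")
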
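# dynapool

Length-based stock assessment for data-limited fisheries, built around the
classic desk-assessment chain used for river and lake stocks: length–weight
allometry, von Bertalanffy growth, mortality decomposition, and Beverton–Holt
relative yield per recruit.  It ships reference parameter sets for three
schizothoracine cyprinids of the upper Yarlung Zangbo basin (Tibetan Plateau)
— *Schizothorax o'connori*, *Oxygymnocypris stewartii* and *Ptychobarbus
dipogon* — and a synthetic age-structured population generator so every stage
can be validated against known truth.

Intended users: fisheries scientists and quantitative ecologists running
age–length–weight surveys through the standard assessment chain, and anyone
who needs that chain as tested, reusable Python rather than a spreadsheet.

## The model chain

1. **Allometry** — weight follows a power law of body length, `W = a L^b`,
   fitted by OLS on the log–log scale.  `b = 3` is isometric growth; the
   Wald *t*-test of `b = 3` and an ANCOVA-style slope-homogeneity test
   between sexes are included.
2. **Growth** — length-at-age follows the von Bertalanffy function
   `L_t = L∞(1 − e^(−k(t − t0)))`, fitted by nonlinear least squares to
   individual (age, length) pairs.  Derived quantities: weight curve
   `W_t = W∞(1 − e^(−k(t − t0)))^b`, rate and acceleration curves, the
   weight-growth inflection age `t_i = ln(b)/k + t0`, the cohort-biomass
   critical age `t_c = [k t0 − ln M + ln(bk + M)]/k`, and the growth
   performance index `φ = log10 k + 2 log10 L∞`.
3. **Mortality** — total mortality from mean length above the gear-selection
   length, `Z = k(L∞ − L̄)/(L̄ − Lc)` (Beverton–Holt); natural mortality from
   Pauly's empirical formula in `L∞`, `k` and habitat temperature `T`;
   `F = Z − M` and exploitation rate `E = F/Z`, with the standard
   reliability diagnostics (`e^−k < 1`, `M/k ∈ [1.5, 2.5]`, `Z/k > 3`).
4. **Yield per recruit** — the Beverton–Holt relative dynamic-pool model
   `Y′/R = E U^(M/k) [1 − 3U/(1+q) + 3U²/(1+2q) − U³/(1+3q)]` with
   `U = 1 − Lc/L∞` and `q = k/Z = (1−E)/(M/k)`; `B′/R = (Y′/R)/F`.
   Reference points `E_max` and `E_50`, isopleth grids over `(E, Lc/L∞)`,
   and size-limit recommendations averaging the inflection length, the
   critical length and the yield-surface optimum.

A **replay mode** accepts published parameter sets (interval estimates and
mortality coefficients) and recomputes the whole derived chain without raw
samples; a **fit mode** estimates everything from a sample table.

## Worked example

```sh
python examples/replay_reference_stocks.py
```

```
species           t_i    t_c   phi      E  E_max   E_50 min size
S. o'connori    10.77   8.58  4.53  0.546  0.579  0.314     358mm
O. stewartii     8.53   6.93   4.5  0.758   0.88  0.379     311mm
P. dipogon       8.58   6.89   4.5  0.711  0.885  0.379     315mm
```

Reading the first row: *S. o'connori* grows fastest in weight at age 10.77,
an unfished cohort's biomass peaks at age 8.58, and the size-standardised
growth index is 4.53 (typical of high-plateau schizothoracines).  Fishing
currently accounts for 54.6% of all deaths (`E = 0.546`) — above the 0.5
rule-of-thumb but below the yield-maximising `E_max = 0.579`, i.e. moderate
overexploitation.  At `E_max` the stock would hold under 25% of its unfished
biomass, and at `E_50` exactly half.  The recommended minimum capture size
(358 mm) averages three metrics: length at `t_i`, length at `t_c`, and the
optimum of the yield-per-recruit surface over exploitation rate and capture
size jointly.

Other examples cover each capability in isolation: simulating surveys,
allometry testing, growth fitting, mortality decomposition, and the
yield-per-recruit analysis (`examples/*.py`).  A thin CLI mirrors the
pipeline: `dynapool simulate | fit-lw | fit-growth | mortality | ypr | run`.

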
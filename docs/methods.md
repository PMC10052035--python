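# Methods

This note records the models implemented, the defaults and why, the
numerical conventions, and what the synthetic-data generators do and do not
emulate.

## MEP site-pairing model

A molecule's hydrogen-bond donor and acceptor capacity is summarised by the
local maxima and minima of its electrostatic potential on an electron-density
isosurface. The package does not compute these surfaces (no quantum
chemistry, no geometry handling); it starts from a table of extrema.

**α/β conversion.** ESP extrema map to dimensionless interaction-site
parameters through a two-term quadratic with zero constant term, following
the Hunter-school calibration of ESP against hydrogen-bond donor/acceptor
scales:

- donors: α = 1.62·10⁻⁵ V² + 9.62·10⁻³ V with V = ESP maximum in kJ/mol,
- acceptors: β = 1.46·10⁻⁴ V² − 9.30·10⁻³ V with V = ESP minimum in kJ/mol,

so both parameters are non-negative on their admissible domains (V ≥ 0 for
donors, V ≤ 0 for acceptors; sign mismatches are rejected). The coefficients
are configuration, not constants: `site_param_from_esp` accepts any (c₂, c₁)
pair, and the defaults above are the package's transcription of that
published calibration. The internal ESP unit is kJ/mol; tables declaring
kcal/mol are converted at 4.184 kJ/kcal on read.

**Pairing.** Both site lists are sorted by parameter descending and paired
rank for rank over min(n_d, n_a) pairs, E = −Σ αᵢβᵢ. By the rearrangement
inequality this is the minimum (most stabilising) assignment over all
one-to-one pairings, which the test suite verifies by brute-force
enumeration up to six sites a side. Excess sites are reported unpaired and
contribute zero — the natural extension of hierarchical pairing to unequal
site counts.

**ΔE = E_CC − E₁ − E₂** with E₁, E₂ the within-molecule pairing energies.
Method A computes E_CC from the two cross pairings (API donors × coformer
acceptors plus coformer donors × API acceptors); method B merges both donor
lists and both acceptor lists, re-ranks, and pairs hierarchically — so
method B can keep a strong homomeric contact (e.g. an amide–amide dimer of
the API) when it outranks the heteromeric alternatives. No constraint
forcing specific motifs to survive is imposed beyond this ranking; that is
the whole content of the merged-list reading. Only 1:1 stoichiometry is
supported; other ratios are rejected rather than approximated.

**Sign convention.** ΔE < 0 is classified favorable, ΔE = 0 unfavorable
(strict inequality). When ranking coformers, more negative ΔE ranks first
and ties break lexicographically by coformer id. Downstream evaluation
therefore declares ΔE scores as `lower-is-positive`. (One also encounters
the opposite phrasing — "higher ΔE, higher likelihood" — in informal use
where ΔE denotes the energy *gain*; this package consistently uses the
difference as defined above.)

Useful identities exercised by the tests: ΔE(M, M) = 0 under both methods;
for single-site molecules, ΔE under method A reduces to (α₁−α₂)(β₁−β₂);
scaling all parameters by k scales every energy by k².

## Formation thermodynamics

For x A(s) + y B(s) → AₓBᵧ(s), with activities approximated by molar
concentrations (an activity-coefficient hook exists; any factor common to
the pure-component and cocrystal-equilibrium concentrations cancels in the
ratio, which is why the solvent choice has little influence):

- ln K_f = x ln(a_p,A/a_cc,A) + y ln(a_p,B/a_cc,B); K_sp = a_cc,Aˣ·a_cc,Bʸ.
- Δ_f G = −RT ln K_f, R = 8.314 J mol⁻¹ K⁻¹, reported in kJ/mol.
  Temperatures are kelvin internally; Celsius inputs convert on read.
- Van't Hoff: unweighted ordinary least squares of ln K_f on 1/T;
  Δ_f H = −R·slope, assumed constant over the (narrow, ~20 K) range. The
  quoted uncertainty is the OLS standard error of the slope; with only two
  temperatures the fit is exact and no uncertainty is reported. Identical
  temperatures raise a singular-design error.
- TΔ_f S = Δ_f H − Δ_f G; ln K_f at the reference temperature is read off
  the fitted line, so ΔG = −RT ln K_f and TΔS = ΔH − ΔG hold exactly (to
  1e−9) for every end-to-end result. Uncertainties propagate linearly
  (quadrature for the difference).

**Enthalpy–entropy diagram.** The (Δ_f H, TΔ_f S) plane splits into eight
sectors by the two axes and the quadrant bisectors. The driving-force
category is decided by ΔG = ΔH − TΔS and the dominant term: entropy-driven
when TΔS > 0 dominates with ΔG < 0; enthalpy-driven when both terms are
negative with |ΔH| > |TΔS| (formation favorable, entropy opposing);
cooperative when both terms favour formation (ΔH < 0 < TΔS) with enthalpy
dominant; formation-unfavorable when ΔG ≥ 0. Sector letters: A is the
octant 90°–135° (entropy-driven with ΔH < 0), D is 180°–225°
(enthalpy-driven); the remaining letters B, C, E–H fill the other octants
counterclockwise after A, skipping D's fixed slot. Only A and D carry
meaning; the other letters are conventional labels and should not be
over-interpreted. Boundary ties |ΔH| = |TΔS| in the third quadrant are
assigned to the enthalpy-dominant sector D — an arbitrary, documented
choice.

**Rounding for table-style reports** uses round-half-away-from-zero at the
printed precision; full precision is retained internally and rounding
happens only at render time.

## Eutectic stability

K_eu = [CF]_eu/[Drug]_eu with relative uncertainties combined in
quadrature; S_cc = √([Drug]_eu·[CF]_eu) for 1:1 stoichiometry (other ratios
rejected), with the half-relative-error propagation of a square root.
Stability: K_eu ≤ 1 ⇒ stable (boundary inclusive). Swapping the component
labels maps K_eu to its reciprocal and leaves S_cc unchanged.

## QTAIM energetics

Input records are critical points with signature, ρ_b, ∇²ρ_b and G_b in
atomic units. Retention requires all three of: signature (3,−1), ∇²ρ_b > 0
(closed-shell contact) and ρ_b > 0.003 a.u. — the density cutoff is strict,
so ρ_b = 0.003 is excluded. The 5 Å contact-search radius belongs to
critical-point generation upstream; here it survives only as an optional
distance filter on records that carry a distance. E_int = 1147·G_b kJ/mol;
the linear form makes the round trip E_int/1147 exact to machine precision.
Bond-class labels (conventional vs non-conventional hydrogen bond) are
annotations taken from input, never inferred from geometry.

## Screening-model evaluation

Scores are normalized so that higher always predicts cocrystal formation
(`lower-is-positive` scores are negated), and a record is predicted positive
iff its normalized score strictly exceeds the cutoff (default 0 — the
natural cutoff for ΔE-type and propensity-difference scores). Sensitivity,
specificity and accuracy are percentages; balanced accuracy is the mean of
the *unrounded* rates, then rounded half-away-from-zero to one decimal — one
fixed rule applied uniformly. Methods may be evaluated on different coformer
subsets (scores are not always available for every pair); each row reports
its own denominator rather than assuming a common one, and conflicting
outcome labels for the same coformer across methods are rejected.

The ROC curve is the standard threshold sweep over all distinct scores; AUC
is its trapezoidal area, which equals the Mann–Whitney statistic
P(score⁺ > score⁻) + ½P(tie). Both routes are implemented (threshold sweep
via scikit-learn; the pair statistic directly) and the test suite asserts
their equality on random tied fixtures and against scipy's Mann–Whitney U.

## Synthetic-data generators

All generators are pure functions of their arguments including the seed
(numpy `default_rng`), so identical configuration reproduces identical
bytes.

- **Solubility series**: the generative truth is ln K_f(T) = −ΔH/(RT) + ΔS/R.
  Defaults emulate the enthalpy-driven benchmark cocrystal: ΔH = −9.5 kJ/mol,
  ΔS chosen so TΔS(298.15 K) = −2.4 kJ/mol, five temperatures 293.15–313.15 K
  in 5 K steps, triplicate measurements with 2% multiplicative lognormal
  noise (solubilities are positive and errors scale with the value;
  replicate means are stored). Pure-component baselines are arbitrary smooth
  increasing exponentials of T — only pure-to-cocrystal ratios enter ln K_f,
  so their absolute form is immaterial. The mean-one lognormal noise biases
  each log-concentration by the same amount, which cancels between numerator
  and denominator of ln K_f, so the van't Hoff estimate is unbiased — the
  tests verify this over 200 replicate simulations.
- **Screening scores**: positives ~ N(d, 1), negatives ~ N(0, 1). Defaults
  d = 1.19 (population AUC Φ(d/√2) ≈ 0.80) with 55 positive and 32 negative
  pairings, the size of the experimental benchmark.
- **Site tables**: ESP extrema uniform in sign-consistent ranges (defaults
  ±[50, 220] kJ/mol, spanning typical hydroxyl/amide extrema).
- **Critical points**: exactly round(n·fraction) records pass the retention
  filter; each failing record violates exactly one condition, chosen at
  random.

What the generators deliberately do **not** emulate: molecular structure
(sites have no geometry, so steric accessibility and metric complementarity
of real synthons are absent), temperature-dependent ΔH (the van't Hoff line
is exactly straight), activity coefficients (set to 1), and correlated
measurement errors between components measured in the same run. Passing
tests therefore demonstrate the estimators' correctness under the stated
statistical model, not the accuracy of MEP screening or
concentration-as-activity approximations on real systems.

## Problem sizes and limitations

The test suite and the acceptance script use: 1,000 (tests) / 200 (script)
random pairing fixtures at ≤ 6 sites per list for brute-force optimality;
5,000 scores per class for the Gaussian-AUC check (3 Hanley–McNeil standard
errors); 200 simulations for van't Hoff unbiasedness (2 Monte-Carlo standard
errors). Known limitations: only 1:1 stoichiometry for ΔE and S_cc;
matched-temperature solubility input is required (no interpolation across
temperature grids); no ternary phase diagrams, congruency prediction, or
pH-dependent solubility; HBP and machine-learning screening scores are
consumed as inputs, never generated.
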
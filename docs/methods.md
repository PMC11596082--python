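# Methods

## Scope and model

`solutherm` analyses rectangular solubility grids — mole-fraction solubility
`x3(w1, T)` of one solute over compositions of a binary solvent blend and a
common set of temperatures — under the standard dilute-solution assumptions
of the cosolvency literature: ln x3 linear in 1/T over the studied window
(no heat-capacity curvature in solution), a single unchanging solid phase,
and log-linear blending between the pure solvents for the predictive model.
The bundled dataset (sulfamerazine in acetonitrile + ethanol, 21 × 9,
278.15–318.15 K) satisfies these to within its measurement uncertainty.

## Solution thermodynamics (van't Hoff–Krug)

Each composition is fitted by unweighted OLS of ln x3 on `(1/T − 1/Thm)`,
with `Thm` the harmonic mean of the temperature levels. Because the mean of
1/T over the levels equals 1/Thm exactly, the regressor is mean-centered:
the intercept is the mean of ln x3, slope and intercept estimates are
orthogonal, and the functions at Thm follow as ΔH° = −R·m, ΔG° = −R·Thm·a,
ΔS° = (ΔH° − ΔG°)/Thm. The decomposition ΔG° = ΔH° − Thm·ΔS° therefore
holds to round-off by construction, and ζH + ζTS = 1 exactly.

Uncertainties are propagated from the regression standard errors treating
slope and intercept as independent (justified by the mean-centering):
u(ΔH°) = R·se(m), u(ΔG°) = R·Thm·se(a), u(ΔS°) = √(u(ΔH°)² + u(ΔG°)²)/Thm.
Published tables of this kind rarely state their ± provenance; ours are pure
regression errors and may differ from any replicate-based values. They are
reported, not asserted against external numbers. With nine temperatures the
standard errors carry 7 degrees of freedom, so a ±3·SE interval covers the
truth with probability P(|t₇| ≤ 3) ≈ 98%, not the Gaussian 99.7% — the
calibration test asserts accordingly.

Weighted fits (by u(x3)) are deliberately not the default: the reference
analyses in this field use plain OLS, and the bundled data's uncertainties
are nearly proportional to x3, which makes weights on ln x3 almost uniform.

`R = 8.31446 J mol⁻¹ K⁻¹` throughout; energies are reported in kJ mol⁻¹,
entropies in J mol⁻¹ K⁻¹.

## Ideal solubility and mixing functions

The ideal (interaction-free) solubility uses the fusion cycle with a
heat-capacity correction:

    ln x_id(T) = −(ΔfusH/R)(1/T − 1/Tm) + (ΔCp/R)[(Tm − T)/T − ln(Tm/T)].

`dCp_mode` selects the ΔCp convention: `fusion-entropy` (default,
ΔCp = ΔfusH/Tm), `explicit`, or `zero`. The fusion-entropy form is the
default because, with the bundled solute's fusion constants
(ΔfusH = 41.3 kJ mol⁻¹, Tm = 508.5 K — the literature consensus row; the
package's alternative DSC preset 41.5/508.1 gives indistinguishable
results), it is the convention consistent with the bundled study's own
solution-minus-mixing differences (ΔH_id ≈ 24.2, ΔG_id ≈ 12.9 kJ mol⁻¹); the
uncorrected form would put ΔH_id at the full 41.3 kJ mol⁻¹. Mixing functions
are the component-wise differences Δmixf° = Δsolnf° − Δidf°, so the closure
solution = ideal + mixing is exact. The ideal term is treated as error-free
when propagating uncertainties: the fusion-constant uncertainties (±0.5
kJ mol⁻¹, ±0.5 K) contribute well under the regression errors and no
published convention exists for including them.

## Enthalpy–entropy compensation

OLS of ΔsolnH° (y) on ΔsolnG° (x) across compositions, the orientation of
Bustamante's diagnostic: slope > 0 ⇒ enthalpy-driven, < 0 ⇒ entropy-driven.
No weighting; no compensation-temperature extraction (that belongs to the
ΔH–ΔS form, which this package does not use). Degenerate inputs (fewer than
3 rows, zero variance in ΔG°) raise rather than return NaN.

## Cosolvency model and validation

The hybrid model blends two pure-solvent van't Hoff lines log-linearly in
mass fraction. The default fit uses only the two extreme-temperature cells
of each pure-solvent column (exact two-point construction); `all-temps`
refits each pure column over every temperature instead. The solvent-1 term
(weight w1) is always fitted to the w1 = 1 column.

Validation reports MRD = (100/N) Σ |xE − xC| / x_ref and the r² of xC vs xE
on the solubility scale (the parity-plot convention, not log scale). The
absolute-value convention is used because a signed mean cancels; the signed
mean is reported alongside. The reference denominator is selectable:
`experimental` (xE, the textbook convention and the package default) or
`calculated` (xC). Both are legitimate relative-deviation measures and they
differ by ~0.8 percentage points on the bundled grid (6.9% vs 6.1%); the
bundled study's reported statistic corresponds to the calculated-reference
convention, which is what the reproduction script uses. Every run log
records the convention in force.

## Synthetic grids

The generator draws x3(w, T) = exp[w(a1 + m1/T) + (1−w)(a2 + m2/T)]·ε with
ε lognormal, unit mean, chosen CV (ln ε ~ N(−σ²/2, σ²), σ² = ln(1 + CV²)) —
multiplicative on x3, hence additive on ln x3, the scale every regression
uses. Defaults reproduce the bundled study's design: 21 × 9 grid,
278.15–318.15 K, truth coefficients equal to the published four-parameter
model, CV = 2% (commensurate with the measured table's relative standard
uncertainties, which run ~0.3–3%). A single seeded `numpy` Generator owned
by the spec gives bit-reproducible grids. The generator emulates exactly the
structure the analysis assumes — it contains no van't Hoff curvature,
deviations from log-linear blending, polymorph transitions, or
heteroscedasticity beyond the lognormal factor — so recovery tests validate
the estimation chain, not the physical adequacy of the model for real
systems.

Parameter-recovery checks run 500 seeded replicates of the full design at
CV = 2% (a few seconds of CPU) and require the mean bias of the fitted ΔH°
to stay below 1% of truth at every composition; noiseless grids must be
recovered to 1e-9.

## Numerical choices and degenerate inputs

- Temperatures are matched with absolute tolerance 1e-6 K when checking grid
  rectangularity (text round-trip safety); w2 is always computed as 1 − w1.
- Input dialects make the x3 scale explicit (`x3_scale`) because solubility
  tables are customarily printed as 10⁴·x3.
- Two-point construction and ≥3-point regression are separate code paths;
  a 2-point "fit" through `fit_vant_hoff` is an error, not a silent exact fit.
- ζ partition with ΔH° = T·ΔS° = 0 is undefined and raises; predictions at
  w1 outside [0, 1] require an explicit `extrapolate=True`.
- The ideal-solubility model refuses T > Tm (solid phase assumption).

## Known limitations

- No activity-coefficient or multi-parameter cosolvency correlations
  (Jouyban–Acree, Wilson variants): the package stops at the log-linear
  hybrid by design.
- No curved (ΔCp-in-solution) van't Hoff variants; strongly curved data will
  show it only through poor r² per composition.
- Mixing-function uncertainties ignore fusion-property uncertainty (see
  above), so they are lower bounds when fusion constants are poorly known.
- The EEC diagnostic is a descriptive regression; it does not test causal
  compensation mechanisms.
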
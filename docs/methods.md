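# Methods

## Model structure and assumptions

The package implements an unstructured (non-segregated, lumped-biomass)
kinetic model of propionic-acid fermentation. Its assumptions are the
usual ones for this organism grown on defined medium at controlled pH:

- sucrose is the single limiting carbon source; nitrogen is in excess;
- propionic and acetic acid are the only inhibitory metabolites, acting
  non-competitively on sucrose uptake;
- pH is controlled (6.5) throughout, so no pH dynamics are modelled;
- products follow the Luedeking–Piret decomposition: a growth-associated
  coefficient `K` (g product per g new biomass) plus a non-growth
  specific rate `β` (g·g DCW⁻¹·h⁻¹);
- pyruvate is both excreted and re-consumed; its re-consumption is a
  shared Michaelis term `f = PYR/(PYR+K_pyr)` feeding acetate (K5) and
  succinate (K7). Carbon consistency between the drain (K3) and the
  gains (K5+K7) is *not* enforced — the rate equations do not couple
  them stoichiometrically; a warning is logged when K3 < K5+K7.

Growth is maintenance-corrected, `µ = (qs − ms)·Yxs`, and may be
negative when uptake falls below maintenance — late-phase biomass
decline is a real feature of the model, not an error.

Lactate is deliberately absent from the state vector: it is routinely
measured in this fermentation but not modelled; readers preserve a
lactate column as an annotation.

Biomass is canonicalised to g DCW/L. Absorbance inputs are converted
with strain-specific linear factors (0.29 g/L per A600 unit for the
wild-type strain, 0.25 for the high producer).

## Numerical integration

`simulate` uses LSODA (stiff-capable, adaptive) at rtol 1e-8 /
atol 1e-10. Piecewise-constant feed profiles make the fed-batch RHS
discontinuous in time, so every feed-segment boundary is a hard restart
point: the solver integrates segment by segment and never steps across
a switch.

Non-negativity is handled in the rate laws, not by clipping states:
`qs` vanishes with the Monod term as S→0 and the pyruvate drain with
`f` as PYR→0. One case is not covered by those saturations: when µ < 0
a growth-associated production term turns consumptive and could push an
exhausted product negative. Net negative product rates are therefore
faded linearly to zero over the final 1e-6 g/L — continuous (so the
adaptive solver does not chatter at the switching surface) and five
orders of magnitude below the 0.05 g/L detection limit. Output values
in (−1e-6, 0) are snapped to exactly 0. Trajectories are compared
against a fixed-step RK4 oracle in the tests; for species pinned at
exhaustion the comparison uses an absolute floor (1e-5 g/L) because a
relative tolerance is meaningless at zero.

In fed-batch runs an optional augmented state integrates cumulative
consumed sucrose, enabling an exact mass-closure audit
(V·S − V₀·S₀ + consumed − fed = 0, which the bundled scenario satisfies
to better than 1e-5 relative).

## Parameter estimation

The objective stacks per-species residuals (observed − simulated at the
observed times), each normalised by the species' maximum observed value
so that sucrose (~80 g/L) does not drown pyruvate (~1 g/L). Rows with a
missing species are dropped per species, not per row. Minimisation uses
scipy's trust-region-reflective `least_squares` with finite-difference
Jacobians, per-parameter bounds (β terms bounded below at −1 g·g⁻¹·h⁻¹,
allowing net non-growth consumption), and optional multi-start: 5
log-normally jittered copies of the initial guess, deterministic in the
seed. A failed candidate simulation returns a large finite penalty
residual instead of raising, keeping the optimizer alive. Ks is
normally held fixed and estimated separately (`fit_monod_ks`) from
serum-bottle uptake rates measured at several sucrose levels, where
products — hence inhibition — are negligible; that fit is a plain
two-parameter Monod least squares with covariance-derived standard
errors.

Reliability is the mean per-variable coefficient of determination
`R² = (1/m) Σ (1 − SSE/SST)` over all species present with nonzero
variance (zero-variance species are excluded with a warning and m
shrinks). Negative contributions are allowed — the model can be worse
than the observed mean.

## Feeding-strategy design

Candidates are single-segment constant feeds (rate F over
[t_start, t_end], feed sucrose So), scanned exhaustively over a user
grid — matching the strategy actually realised in practice; arbitrary
piecewise-constant profiles can still be evaluated one-off. The sugar
ceiling (default 40 g/L) is a path constraint checked on a dense output
grid (default 0.1 h), not only at sampling times. It is enforced from
the candidate's feed-start time onward: the ceiling guards against
feed-driven accumulation, and the initial batch phase may legitimately
start above it (the bundled culture starts at 80 g/L) and burn the
sugar down before feeding begins. A zero-feed candidate is checked over
the whole horizon. Ranking maximises final PA; ties break to lower
total fed sucrose, then lower rate.

## Performance metrics

- µ: slope of ln X vs t on the mid-exponential window — the contiguous
  window (default 4 points, configurable; "mid-exponential" has no
  standard width) maximising the R² of the log-linear fit with positive
  slope, earliest window on ties.
- Pv: ΔPA/Δt over a fixed interval, default 15–30 h, endpoints linearly
  interpolated (sampling is every few hours in practice).
- Yps: total PA formed over total sucrose consumed; totals are
  concentration×volume differences, so fed-batch values account for fed
  mass and volume change.
- PA:AA, PA:SA: ratios of whole-run totals; a zero denominator reports
  +inf with a warning rather than raising.
- qs, qp: |slope| of the species-vs-biomass regression on the
  mid-exponential window, times µ; both reported as positive magnitudes.

## Intracellular pH

The BCECF emission ratio R = (S490−S440)/(F490−F440) — filtrate
subtraction is the sole background correction — is inverted through a
per-strain calibration curve acquired at pH 4–8 with
ionophore-equilibrated cells. The calibration functional form is not
standardised, so the default is a monotone piecewise-linear interpolant
through the replicate-averaged nodes (exact at nodes, no extrapolation);
a 4-parameter logistic fit is available behind a flag for smoother
inversion between nodes. Averaged node ratios must be strictly monotone
in pH or the calibration is rejected. ΔpH = pHi − pHex.

## Synthetic data and what it does (not) show

The generator produces exactly the data the estimators expect:
trajectories from the model itself with multiplicative Gaussian noise
(default cv 5%, the magnitude-proportional error typical of HPLC
concentration measurements) and a 0.05 g/L detection floor; Monod rate
tables; and fluorescence readings with fixed filtrate intensities so
the ratio denominator never degenerates. Every generator stores its
ground truth in the output metadata and is bit-reproducible under a
fixed seed.

Two frozen reference parameter sets define the bundled study
conditions. They were calibrated once against the published performance
figures of a 2-L fermentation campaign — high-producer batch: final PA
44.21 g/L, Yps 0.62 g/g, PA:AA 5.45, PA:SA 6.19, Pv 0.955 g/L/h from
80 g/L sucrose; wild type: 26.28 g/L, 0.45 g/g, 2.95, 6.28,
0.53 g/L/h; high-producer fed-batch: ≈70 g/L PA with a 0.0066 L/h feed
of 350 g/L sucrose over 40–64 h at V₀ = 0.7 L, sucrose staying below
40 g/L — and are now version-pinned; changing them is a breaking
change. The batch scenario spans 72 h (the scale of the underlying
batch runs), the fed-batch 140 h, sampled every 4 h by default.
Absolute mid-exponential growth rates are not among the published
figures; the calibration used 0.20/0.14 h⁻¹ (the reported 43%
improvement of the producer over the wild type) as soft targets, and
the realised scenario values are 0.16/0.14 h⁻¹.

Because recovery tests consume data generated by the model itself, they
demonstrate estimator correctness (the optimisation recovers the
generating parameters under realistic noise), not model adequacy for
any particular real culture: real data add model mismatch,
autocorrelated sampling error and lactate, none of which the generator
emulates. The recovery experiments use 25 samples over 100 h,
triplicates pooled by averaging, with 5 of the 18 parameters free
(rs_max, Yxs, K1, kipa, β_pa) — the subset that dominates the sucrose
and PA trajectories; freeing all 18 on a single trajectory is not
identifiable and is not claimed.

## Known limitations

- No structured/stoichiometric (flux-based) metabolism, no pH dynamics,
  no lactate state, no gas phase.
- The fed-batch design optimises a single constant-rate segment; no
  optimal-control solution for continuous F(t).
- Parameter uncertainty is limited to least-squares standard errors for
  the Monod fit; no Bayesian/MCMC machinery.
- The β sign convention permits net non-growth consumption down to
  −1 g·g⁻¹·h⁻¹ during fitting; the bundled reference sets use only
  non-negative β values.
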
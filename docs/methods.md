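# Methods

## Model and assumptions

The telegraph scheme treats one gene as four first-order reactions:
transcription at β_m (h⁻¹), message decay at γ_m (message lifetime
τ_m = 1/γ_m), translation at β_p per message, and protein depletion at γ_p.
Under rapid growth most protein is lost by dilution, so γ_p = ln2/T with T
the doubling time; an explicit γ_p can be supplied instead, in which case
the gamma shape parameter is β_m/γ_p and the derived message number
k·ln2 no longer equals β_m·T (active degradation inflates the noise — the
package reports the k-based value and documents the divergence).

The stationary protein distribution is gamma, Np ~ Γ(k, θ), with
k = β_m/γ_p = μ_m/ln2 and θ = ε·ln2, where μ_m = β_m·T is the message
number per cell cycle and ε = β_p/γ_m the translation efficiency. The two
consequences used throughout are μ_p = μ_m·ε and CV²_p = ln2/μ_m. The noise
law assumes ε ≫ 0 (many proteins per message burst); `protein_stats` warns
below ε = 5, a threshold chosen here since the underlying approximation has
no sharp cutoff. Transcriptional bursting and active protein degradation,
both of which only increase noise, are out of scope; the floor estimates
are therefore conservative.

All internal times and rates are in hours. Organism constants JSON accepts
`*_min` key variants for minute-denominated sources. Printed-table helpers
round half-away-from-zero to one (threshold tables) or two (constants
tables) significant figures; computation always keeps full precision.

## Simulator

`telegraph.simulate` is a direct-method (exhaustive propensity scan)
Gillespie SSA. Populations are desk-scale, so exact SSA is affordable; no
tau-leaping. The loop is vectorized across independent cells (one
synchronous numpy step per event index), which keeps 2×10⁴-cell ensembles
in the low seconds. Independent cells, rather than one long trajectory,
avoid autocorrelation in ensemble statistics.

Two division treatments are provided because the gamma parameters are
stated for protein number *at cell birth*:

- `continuous_dilution` (default): depletion as a first-order reaction at
  γ_p; one sample per cell after a burn-in of ≥5 (default 10) protein
  lifetimes. The steady-state mean is μ_m·ε/ln2.
- `explicit_division`: γ_p = 0 within a cycle, binomial (p = 1/2)
  partitioning of both species every T, sampling at birth after ≥10 cycles.
  The birth mean is μ_m·ε.

The modes differ by that ln2 factor in the mean; both give
CV²_p ≈ ln2/μ_m. For the continuous mode the exact master-equation noise is
1/⟨p⟩ + (1/⟨m⟩)·γ_p/(γ_m+γ_p), which for the rapid-growth parameter regime
used in the tests (ε ≥ 30, τ_m ≪ T) sits within ~3% of ln2/μ_m — inside the
10% band the simulation tests assert. Cells whose total propensity reaches
zero (β_m = 0 with empty state) are frozen and sampled as-is. The SSA state
is piecewise constant, so the state carried past the sampling time *is* the
state at the sampling time.

## Estimators

**Noise model.** CV²_p = b·μ_p^(−a) + c is fit by least squares on
log10 CV² (noise spans decades; scatter is treated as lognormal — the
choice is declared, not derived). Bounds b, c ≥ 0, a ∈ [0, 3]; the
canonical null pins a = 1. Five deterministic starts over the exponent grid
{0.3, 0.5, 1, 1.5, 2} (amplitude/floor re-seeded from the data at each
start) guard against local minima. Genes at or below the abundance
detection threshold (default 10 molecules, the autofluorescence scale of
fluorescence assays; configurable) are excluded and counted. The
log-likelihood profiles out the residual variance; standard errors come
from the Jacobian at the optimum. A floor driven to its lower bound is
flagged (`c_at_bound`) since its SE is then unreliable.

**Canonical-scaling test.** The null (a = 1) is nested in the alternative;
2Δlogℓ is referred to χ²₁. With the variance profiled this equals
n·ln(RSS₀/RSS₁). Calibration is checked empirically (200 seeded replicates:
type-I error ≈ 5%, p-values uniform) along with power against a = 0.5 at
n = 3000.

**Translation law.** OLS of log10 μ_p on log10 μ_m (statsmodels), reporting
the covariance of (log10 amplitude, exponent). Measurement error in μ_m is
deliberately ignored — the law's only job is to map abundance onto message
number, so no errors-in-variables correction is applied. Composing the
inverted law with CV² = ln2/μ_m gives the derived noise law
(ln2·B^(1/A), −1/A) and efficiency law (B, A−1), both parameter-free given
the translation fit.

**Gamma fits.** Method of moments (k = mean²/var with unbiased variance,
θ = var/mean), robust to the simulator's discrete and occasionally zero
counts; optional MLE refinement (scipy, location pinned at 0) drops zeros
with a warning.

## Floor analysis

`annotate_gene_table` fills μ_m = (T/τ_m)·μ_m/c and β_m = μ_m/T exactly and
idempotently. Class histograms are log10-uniform over the observed positive
range (40 bins by default, a visual-scale choice) with zeros tallied in a
separate bin — silent genes are real data, not missing data. The floor
report exposes both fixed-threshold fractions (strictly below μ_m = 1) and
the 1%/5%/50% class quantiles (linear interpolation between order
statistics, since class tails are small), rather than committing to one
operational floor definition; the implied noise ceiling ln2/μ_m is
evaluated at the 1% quantile. Essentiality is taken as a given binary
label; its context dependence (conditionally essential genes under other
growth conditions) is a caveat for interpretation, not computation.

## Synthetic data

The generator emulates the structure the analysis assumes, not any specific
published dataset. Message numbers are lognormal per class — a family
chosen to mimic peaked log-scale distributions (essential genes peaked near
15 messages per cycle); the essential class is truncated at the floor
(resampling, with a hard cap after which the configuration is rejected as
infeasible) except for a planted leak fraction kept below it, reflecting
that the observed floor is a sharp cutoff rather than a hard limit. Zeros
model silenced nonessential genes. Protein means follow the configured
power law with lognormal scatter; CV² is ln2/μ_m plus a floor with
multiplicative lognormal measurement error; sub-threshold proteins are
flagged (left-censoring), never dropped, so exclusion policy stays with the
fitters. Defaults are yeast-like: 3000 genes, 20% essential, translation
law (8.0, 2.1) with 0.3 decades scatter, noise floor 0.01, 10% relative
noise on CV², detection threshold 10 molecules.

What passing recovery tests show: the estimators are consistent and
calibrated under the generator's assumptions (lognormal scatter,
independent genes, exact power laws). What they do not show: robustness to
the correlated measurement error, normalization uncertainty, and
condition-dependent expression of real proteome datasets.

## Problem sizes and numerics

Simulation checks use 2×10⁴ cells for the noise-ceiling measurement (the
sampling SE on CV² is then ~1.5%, comfortably inside the 10% assertion
band) and 2–8×10³ cells for mean/shape checks; calibration studies use 200
replicates of n = 2000 and power studies 50 replicates of n = 3000. These
sizes put every statistical assertion at least ~3 standard errors from its
boundary under the planted conditions. Optimizer tolerances are 1e-14
(xtol/ftol/gtol) so noiseless-limit tests recover planted parameters to
≥4 decimals; degenerate inputs (single distinct abundance, zero variance,
empty classes) raise rather than returning unstable estimates.

## Known limitations

- The gamma model's low-ε corrections are warned about, not modeled.
- The continuous-dilution mode measures a time-averaged ensemble, not the
  birth ensemble; the ln2 mean factor between modes is documented above.
- The noise-model error model (lognormal in CV²) and the LR test are this
  package's declared choices; other error models would change p-values but
  not the direction of the canonical-scaling rejection at these effect
  sizes.
- Organism constants are representative point values; no uncertainty is
  propagated through the floor estimates.
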
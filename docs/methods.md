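# Methods

## Transcriptional activity calling

**Model.** For a bulk RNA-seq gene table, the density of log2-transformed
TPM (and, in parallel, FPKM) values of all genes with nonzero expression is
modelled as the sum of two unnormalized Gaussian curves — an inactive
(low-mean) and an active (high-mean) component. The y-axis of the density is
a gene count, so the fit uses curve *amplitudes* (heights in count units),
not mixture weights: the activity cutoff is defined on the relative rates of
active vs inactive genes at a given expression level, which is exactly the
ratio of the two fitted curves.

**Procedure.**

1. Exact zeros are excluded before the log transform (no pseudocount); they
   are counted and the genes reported with call `zero`. A pseudocount would
   smear the zero mass into the inactive mode and bias its mean.
2. log2 values are rounded to one decimal, half away from zero
   (spreadsheet-style), and tallied into contiguous 0.1-wide bins with
   zero-count gaps kept. Bin identity is computed in integer deci-units so
   no value migrates across a bin boundary through float drift.
3. The six parameters (A_a, μ_a, σ_a, A_i, μ_i, σ_i) are fitted to the bin
   counts by unweighted nonlinear least squares (scipy `curve_fit`,
   trust-region reflective, amplitudes ≥ 0, σ ≥ 10⁻³). Initialization is
   deterministic — the two highest-count local maxima at least 1.0 log2
   units apart seed the means (falling back to the highest bin far enough
   from the first peak when the density has no second local maximum), the
   counts at those bins seed the amplitudes, σ starts at 1.0 — so a given
   density always yields the same fit, with no random restarts. Components
   are labelled by fitted mean (active = larger), never by seed order.
4. Degeneracy checks: a σ collapsed to its bound, an amplitude
   indistinguishable from zero, or the two fitted means within one bin
   width of each other raise a fit error carrying the fitted parameters.
   The last case is how a genuinely unimodal density usually manifests:
   the optimizer splits one mode into two co-located components whose
   amplitudes are not identifiable.
5. The cutoff x\* solves A_a φ_a(x) = r · A_i φ_i(x) with r = 5 by default.
   The log curve-ratio is quadratic in x, so the roots are closed form.
   The returned root is the one beyond which the ratio stays ≥ r for all
   larger x within the support of the fitted mixture (means + 6σ): for
   σ_a > σ_i that is the larger root; for σ_a = σ_i the single root of the
   linear equation; for σ_a < σ_i the ratio eventually falls back below r,
   so the lower root is accepted only when the fall-back point lies beyond
   the support — otherwise no meaningful cutoff exists and an error is
   raised. Restricting the for-all condition to the support is deliberate:
   beyond μ + 6σ both curves are numerically zero and their ratio is
   noise. A gene is active iff its log2 value strictly exceeds x\*
   (a value exactly at the cutoff is inactive).
6. TPM and FPKM are analysed independently; the combined call is `active`
   only when both metrics agree (configurable to either-metric). The
   conjunction is the conservative choice when the two analyses are meant
   to corroborate each other; a zero in either metric makes the combined
   call `zero`.

**Numerical notes.** Rounding half away from zero differs from numpy's
banker's rounding only on exact `.x5` boundaries; bin assignment is
insensitive elsewhere. The fit is to raw counts, so high-count bins dominate
the least squares — appropriate when Poisson noise grows only as √count.

## Electrophysiology

**GHK dilution potential.** For a monolayer separating NaCl baths (apical
diluted to 75 mM, basolateral 150 mM; mannitol balancing osmolarity is
treated as electroneutral and ignored), the Goldman–Hodgkin–Katz voltage
with β = P_Na/P_Cl is

V = (RT/F) · ln[(β·Na_ap + Cl_bl)/(β·Na_bl + Cl_ap)].

Concentrations, not activities, enter the expression. The sign convention is
fixed operationally: a cation-selective junction (β > 1) yields a negative
potential upon apical dilution, an anion-selective one a positive potential,
and β = 1 gives exactly 0 mV. V is strictly decreasing in β and bounded by
the two Nernst limits ±(RT/F)·ln 2 (±18.5 mV at 310.15 K for a 2:1
dilution); exponentiating makes the expression linear in β, so the inverse

β = (u·Cl_ap − Cl_bl)/(Na_ap − u·Na_bl),  u = exp(VF/RT)

is closed form and round-trips with the forward model to better than 10⁻⁹
relative. A potential at or beyond a Nernst limit has no positive solution
and raises an out-of-range error. R and F are CODATA values from
scipy.constants; default temperature is 310.15 K (37 °C chamber).

**Blank correction.** The potential measured across a cell-free filter under
the same dilution is subtracted from every cell reading before inversion.

**Conductance.** G_t = (I/V)/A from a single open-circuit (V, I) pair; with
I in µA and V in mV the quotient is directly in mS, divided by the exposed
window area (cm²). Zero current is an open circuit (G_t = 0); nonzero
current at zero voltage is rejected as a short. Multi-point I–V regression
is out of scope. Note the duality TER (Ω·cm²) = 1000 / G_t (mS·cm⁻²).

**Selectivity classification.** Cation-selective if β exceeds the
neutral-pore baseline 50.11/75.23 ≈ 0.666 (the ratio of the free-solution
molar ionic conductivities of Na⁺ and Cl⁻ — what a charge-blind water-filled
pore would show), anion-selective below it, neutral within 10⁻⁶ relative.

**Replicate summaries.** Group statistics are mean and sample SD (ddof = 1)
of the per-record corrected potential, inverted ratio and conductance. For
n = 1 the SD is reported as not-available (NaN), not 0, to avoid spurious
precision; group selectivity is classified on the group mean ratio.

## Barrier assays

**TER.** Per filter, TER = (R_cell − mean R_blank) × growth area. The
default area is 1.12 cm², the manufacturer's nominal growth area of a 12-mm
insert. A reading below the mean blank gives a negative TER: it is flagged
and warned about but not clamped, since it indicates a measurement problem
the user should see.

**Papp.** Papp = (dQ/dt)/(A·C₀). Defaults mirror a standard fluorescein
assay: C₀ = 200 µM (2×10⁻⁷ mol·cm⁻³) dosed in 250 µl apically, 1 ml basal
volume, dt = 2 h. Fluorescence is converted to amount through a single
linear gain (intensity per mol·cm⁻³ of basal concentration) — a
user-supplied standard-curve slope fits the same slot. Intensities below the
blank clamp to zero (with a warning) so detector noise near the limit cannot
produce negative permeabilities. The formula is the simple sink-condition
linear regime: no back-flux or apical-depletion correction over the 2-h
window, and no multi-timepoint kinetics.

## Synthetic data

The generators produce exactly the structures the analyses assume, with all
randomness from one seeded numpy Generator per call:

- **Expression**: each gene is independently zero with probability
  `zero_fraction` (default 0.2), otherwise active with probability
  `active_fraction` (default 0.5); log2 TPM is drawn from N(μ_a, σ_a) or
  N(μ_i, σ_i) (defaults 5 ± 1 and 0 ± 1 — a clean two-mode separation
  typical of published log-expression densities). FPKM = 1.5 × TPM times a
  small lognormal jitter (σ = 0.02 in ln-space), so the two metrics agree
  strongly but not perfectly, letting conjunction-vs-either behaviour be
  tested. Truth labels (`active`/`inactive`/`zero`) ride along.
- **Ussing runs**: cell potential = GHK(β_true) + blank + N(0, σ_V)
  (default σ_V = 0.2 mV, typical replicate spread), with one blank record,
  and V/I pairs exactly consistent with a set areal conductance over a
  3-mm (0.0707 cm²) window.
- **Plate**: blank resistances N(mean, SD); cell resistance = blank mean +
  TER_true/A + the same noise; transported amount dQ = Papp_true·A·C₀·dt;
  intensity = blank + gain·(dQ/V_basal) + N(0, σ_I).

Additive Gaussian noise on potentials and intensities is the simplest model
consistent with replicate mean ± SD reporting. With every noise term at 0,
each generator is the algebraic inverse of its analysis stage, so tests can
demand exact (solver-tolerance) recovery of the true parameters.

**What passing tests do not show.** The generators emulate the *statistical
shape* of the data, not its physics: no read-mapping or normalization
artifacts in the expression channel (the mixture is exactly Gaussian, real
densities are only approximately so), no electrode drift, liquid-junction
potentials or activity-coefficient effects in the chamber, no tracer
back-flux or nonlinearity in the plate reader. Parameter recovery on these
inputs validates the arithmetic and the fitting machinery, not the adequacy
of the two-Gaussian or sink-condition approximations for any particular
real dataset.

## Problem sizes

The default test suite fits densities of 20 000 sampled genes (one fixed
seed), checks the GHK round trip on 100 log-spaced ratios in [0.05, 20],
and runs the end-to-end pipeline twice at 8 000–12 000 genes — sizes chosen
to exercise every code path at the sample sizes the analyses are designed
for while keeping a full run in seconds.

## Known limitations

- The activity caller fits the *binned* density by least squares;
  maximum-likelihood EM on raw values would weight the tails differently.
- Only the P_Na/P_Cl ratio is estimated, never absolute permeabilities, and
  only for NaCl dilution (no bi-ionic or tri-ionic protocols).
- The conjunction rule for the combined activity call is a convention;
  with discordant metrics the either-mode gives systematically more active
  calls.
- TER assumes the blank is stable across the plate; a drifting blank biases
  every filter equally.
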
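# Methods

## The feedback model

State variables per animal: remaining self-sperm S(t), mature oocytes O(t),
cumulative fertilized eggs E(t), with t in hours post-L4. Dynamics

    E' = k_f · O · S,   O' = k_o − E',   S' = −E',
    (S, O, E)(0) = (S_0, 0, 0).

Assumptions: oocyte production is constant at k_o until sperm run out
(no gonadal carrying-capacity term — attempts to give the uterus a
carrying capacity produce non-physiological fits at this assay scale, and
oocyte counts stay roughly constant across genotypes); fertilization is
mass-action in O·S, the macroscale limit of dose-dependent MSP signaling;
states are continuous and deterministic, with integer counting noise
entering only in the observation model. Every fertilization consumes one
sperm and one oocyte, so E + S = S_0 and O + E = k_o·t exactly.

Units and defaults: k_o in oocytes/animal/h (physiological range roughly
1–12), k_f in (sperm·h)⁻¹ (~1e-4 to 1e-3, shared default 2.6e-4), S_0 in
cells/animal (~100–500, default 263). Rates are per animal per hour — the
only normalization under which six-animal six-hour counts are comparable
across assays.

## Solutions

Numeric: `scipy.integrate.solve_ivp` with the explicit Dormand–Prince
5(4) embedded pair, rtol 1e-8 / atol 1e-10 by default; these tolerances
leave the conservation relations testable at 1e-6.

Closed form: substituting the conservation relations reduces the system to
S' = −k_f S (S + k_o t − S_0); u = 1/S linearizes it, and the integrating
factor gives an erf-type quadrature. The textbook arrangement contains the
factor exp(k_f S_0²/2k_o), which overflows double precision once that
exponent passes ~709 (k_f = 0.01, S_0 = 500, k_o = 1 gives 1250). The
implementation is rearranged so every exponential argument is non-positive,
using the scaled complementary error function erfcx: with
x = √(k_f/2k_o)(k_o t − S_0), b = √(k_f/2k_o)·S_0, c = √(πk_f/2k_o),

    x ≤ 0:  1/S = e^{x²−b²}(1/S_0 − c·erfcx(b)) + c·erfcx(−x)
    x > 0:  S = e^{−x²} / (e^{−b²}/S_0 + c(2 − e^{−x²}erfcx(x) − e^{−b²}erfcx(b)))

On the x ≤ 0 branch x² ≤ b², so the only cancellation-prone quantity,
d = 1/S_0 − c·erfcx(b) ≈ 1/(2S_0 b²), is damped by e^{x²−b²} ≤ 1; its
absolute rounding error contributes at most machine epsilon relative error
to 1/S. If d rounds non-positive (k_f/k_o far outside the physiological
range) the closed form raises and callers fall back to the numeric solver —
except inside the fit objective, where a closed-form failure means the
optimizer has left the physiological regime and is answered with a penalty
residual instead of an adaptive ODE solve (a wandering Levenberg–Marquardt
step can otherwise push the explicit solver into millions of steps).

Measured over the 100-point grid k_o ∈ [1,10] × k_f ∈ [1e-4,1e-3] ×
S_0 ∈ [100,500] and t ∈ [0,120] h, the two routes agree to ~3e-8 relative
(tests assert ≤1e-6); conservation violations stay below 1e-5 of the
10×-tolerance budget.

Mating adds a sperm jump S(t⁺) = S(t⁻) + n at the mating time (~1000 sperm
per successful mating); the integration simply restarts from the bumped
state and the conservation total becomes S_0 + n.

## Observation model and fitting

An assay observation is (window, n animals, total eggs); the model
prediction is n·(E(t1) − E(t0)). Residuals are formed in rate space —
observed eggs/(animals·width) minus the model's mean window rate — which
weights the five windows equally and makes the mean absolute residual
interpretable in eggs/animal/h.

Per strain, (k_o, S_0) are fitted by `scipy.optimize.least_squares`
(method "lm") on log-parameters; the log transform enforces positivity
without clipped steps and avoids the negative, non-physiological estimates
that an unconstrained carrying-capacity-style parameter invites. k_f is
fixed at the shared panel value 2.6e-4 by default: with windowed counts
from one strain, k_f and k_o shift the rate curve in nearly the same way
(fitting both on a single strain yields a parameter correlation of ~−0.98,
and the fit warns above |ρ| = 0.95). A joint panel fit with one shared
free k_f plus per-strain (k_o, S_0) is available (`share_kf=True`), using
a sparse-Jacobian trust-region solve.

Starting values are moment-based — k_o from 1.2× the peak observed rate,
S_0 from total observed eggs — with five deterministic starts spaced in
log space. The S_0 starts sweep upward over ×¼ to ×64: the moment guess
only counts eggs inside the sampled windows, so for slow layers whose
reproduction extends far beyond the last window it undershoots by an order
of magnitude, and the spurious local minimum in the k_o–S_0 trade-off
valley is reached from below. With this start ladder, noiseless
five-window data reproduce the generating parameters to ~1e-12 relative
across the whole grid; under the study's assay design (6 animals, five
6-h windows, Poisson counts, 10 replicates) median absolute errors are
~1% per parameter, and ~3–5% at one replicate.

Convergence: cost-change and gradient tolerances 1e-12, at most 2000
residual evaluations per start; ties between starts resolve to the first.

## Synthetic panel

Genotypes: biparental selfed RILs. Along a chromosome the inbred genotype
is a two-state Markov chain with switch probability R = 2r/(1+2r) between
adjacent markers (r from Haldane's map function), the closed-form limit of
selfing to fixation; a brute-force multi-generation selfing simulator is
kept in the package and the two agree on recombinant fractions within
binomial error. Default map: 6 chromosomes (I–V, X) × 32 markers at 5 cM.
No residual heterozygosity, segregation distortion or genotyping error is
simulated.

QTLs add allelic effects (B − A) to k_o and/or S_0, additively with an
optional product-interaction term; parameters driven non-positive raise a
configuration error naming the strains. Default architecture: focal locus
k_o −5.2 on II, modifier k_o −1.0 on X (the two effect magnitudes used in
the sign-epistasis-zone analysis), S_0 +40 on V, on a baseline of
k_o = 11.2, S_0 = 263 for the all-A genotype — so the B-lineage allele
lowers early oocyte production and the sperm-count locus raises fecundity.

Counts: eggs ~ Poisson(n_animals·ΔE) per replicate — the natural noise
model for small-integer egg counts; real assay variance likely exceeds
Poisson (handling, staging, plate effects), so recovery errors measured
here are a lower bound on real-data errors, and passing tests certify the
machinery, not field accuracy. Assay windows default to [18,24], [30,36],
[42,48], [60,66], [84,90] h post-L4 — five 6-h windows spanning the
reproductive span with the anchor points of the study design; the exact
real windows are not published, so these are explicit config-first
stand-ins.

## QTL scans

LOD at a marker = (n/2)·log10(RSS_null/RSS_full) under OLS with a normal
model; genotypes are 0/1 (no dominance term in an inbred panel). Scan
variants share the null intercept(+covariate) model: single (full adds the
marker), additive covariate (full adds the marker to intercept+covariate),
interactive covariate (full adds marker and marker×covariate);
lod_int_only = interactive − additive isolates the interaction. All scans
are evaluated by projecting out the null design once and solving the 1×1
or 2×2 normal equations for all markers and all phenotype columns in a few
matrix products, so a 1000-permutation genome-wide threshold on a 94×192
panel costs ~0.1 s. Numerical policy: markers monomorphic in the retained
strains report LOD 0 with a flag; exact fits are capped at LOD 50 with a
perfect-fit flag; a phenotype fully explained by the null model (e.g.
constant) reports LOD 0 everywhere; strains with missing phenotype are
dropped listwise; peak ties resolve to the lowest cM.

Permutation thresholds: the (1−α) upper order statistic of per-permutation
maximum LODs (ceil((1−α)m)-th of m), a conservative finite-m choice whose
realized genome-wide false-positive rate on null panels is ~5.5% at
α = 0.05 — measured at 0.05–0.06 over 200 panels. With a covariate in the
model, shuffles are stratified within covariate genotype classes by
default, preserving the covariate–phenotype association under the null of
no marker effect; unstratified shuffling is available via a flag.

Bayes credible interval: 10^LOD normalized over one chromosome's markers
as an approximate posterior; the interval grows greedily from the peak,
adding the larger adjacent posterior mass until it holds the target mass.
Flat profiles return the whole chromosome.

## Epistasis analysis

Per time point, all QTLs are fitted jointly: y = Σ main effects + Σ
(modifier × focal) interactions. A QTL's F drops its main effect and its
interaction(s) with the focal locus at once (df 2 for a modifier; 1 + #
interactions for the focal locus); variance explained is the drop-one sum
of squares over total (type-III style). A separate df-1 F drops only the
interaction term. Benjamini–Hochberg runs over the QTL × timepoint family
— separately for the effect tests and for the interaction tests, since the
two questions ("does this QTL matter here?" and "does its effect depend on
the focal background?") have different nulls; the reported `q` is the
effect-family value. Classification follows direction-of-effect
nomenclature: no significant effect → not significant; effect without
interaction → additive; interaction with same-sign effects in the two
focal backgrounds → positive epistasis; opposite signs → negative
epistasis. Effect directions are within-background differences of class
means. An exactly zero effect with a significant interaction classifies by
the same-sign rule and carries a boundary flag.

Sign-epistasis zone: for four genotype classes with k_o = baseline,
+modifier, +focal, +focal+modifier (all positive or the call errors), the
modifier's rate contrast within each focal background crosses zero once;
crossings are bracketed on a 2000-point grid over a horizon of
10·S_0/min(k_o) — several times the slowest class's sperm-exhaustion time
— and polished by Brent bisection to 1e-6 h. The zone is the interval
between the two crossing times. It is empty when the modifier effect is
zero (no contrast) or the focal effect is zero (identical backgrounds,
coincident crossings). As the modifier effect shrinks toward zero with a
fixed nonzero focal effect the endpoints converge continuously, but to the
two backgrounds' marginal-sensitivity sign-change times — a window of
positive width, not a point; only the focal effect going to zero collapses
the zone.

## Pipeline and problem sizes

The CLI stages exchange plain CSV/JSON; each stochastic stage draws an
independent substream of the top-level seed, so runs are reproducible end
to end and stages can re-run in isolation. The validation suite sizes its
simulations for a single CPU: the threshold-calibration measurement uses
200 panels × 200 permutations (the per-panel permutation count reduced
from the study's 1000; the quantile estimator is the same), and the
mapping power/specificity measurement uses 50 seeds per planted-QTL
direction with effects of +1.0 on k_o (baseline 6.0) and +40 on S_0
(baseline 263) — effects sized so a 94-strain panel has high but not
saturated signal at one replicate per window.

## Known limitations

- The model has no gonadal carrying capacity and no cell-level mechanism
  (germline mitosis, oocyte maturation signaling, MSP diffusion); it is
  macroscale by construction and cannot represent, e.g., oocyte-count
  saturation.
- Poisson counting noise understates real assay variance; see above.
- No uncertainty quantification beyond the LM covariance and the
  identifiability correlation (no bootstrap intervals).
- Marker regression only — no interval mapping between markers, no
  multiple-QTL model search.
- With k_f free and single-strain data, (k_f, k_o) are close to
  unidentifiable; estimates there are only meaningful jointly across a
  panel with a shared k_f.
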
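# Methods

## Model

We track a highly polygenic, additive quantitative trait expressed in both
sexes of a diploid, panmictic population of constant size N with
non-overlapping generations. Each segregating biallelic locus i carries
sex-specific per-copy effects (a_{i,f}, a_{i,m}) and a single sex-averaged
derived-allele frequency x_i. Sex-specific mean phenotypes are

    z̄_α = F̃_α + Σ_i 2 a_{i,α} x_i,     α ∈ {f, m},

where F̃_α is the *fixed background* — the contribution of alleles that have
fixed, tracked separately so the long-term equilibration of the mean can be
decomposed into segregating and fixed components.

Selection is sex-specific Gaussian stabilizing selection with overall width
V_S and share factors γ_f, γ_m (γ_f² + γ_m² = 1): the sex-specific widths
are V_{S,α} = V_S/(2γ_α²), so the symmetric default γ = 1/√2 puts equal
selection on both sexes. Under weak selection, linkage equilibrium, and
Hardy–Weinberg proportions, the expected one-generation frequency change of
an allele is

    E[Δx] = [(a_f D_f γ_f² + a_m D_m γ_m²)
             − (a_f² γ_f² + a_m² γ_m²)(½ − x)] · x(1−x)/V_S,

a directional term pulling the sex means (distances D_α = O_α − z̄_α) toward
their optima and a stabilizing term pushing minor-allele frequencies down.
Drift enters by binomial resampling with 2N trials around x + E[Δx], which
has variance x(1−x)/(2N). Mutation adds Poisson(2NU) new alleles per
generation at initial frequency 1/(2N) (a single new copy among 2N gene
copies; an infinite-sites assumption, so U is the genome-wide per-gamete
rate). Per-generation order of operations is selection+drift, boundary
bookkeeping, then mutation; the model is insensitive to this ordering at
the parameter scales used.

### Units

The trait is measured in units of δ = √(V_S/(2N)), the typical equilibrium
fluctuation of the population mean; the default V_S = 2N makes δ = 1. In
these units an allele's squared overall magnitude
a² = a_f²γ_f² + a_m²γ_m² equals its scaled stabilizing-selection
coefficient 2N·s_e, so the architecture is specified directly by the
distribution of a².

### Mutational input

A mutation is drawn as an independent (magnitude, angle) pair: a² is
exponential with mean E(a²), and the angle φ sets the fraction of selection
acting through each sex (cos²φ via females), with effects
a_f = a·cosφ/γ_f, a_m = a·sinφ/γ_m. The default angle distribution h_r
puts probability r on the shared diagonal (a_f = a_m), and (1−r)/2 each on
the female- and male-specific axes, with signs equally likely; the expected
equilibrium intersex correlation is then exactly r. Arbitrary densities
h(φ) are supported provided h(φ) = h(φ+π).

Two reference architectures: *approximately infinitesimal*, E(a²) = 1
(most mutations have 2N·s_e ≲ 4, so infinitesimal-limit predictions hold),
and *multigenic*, E(a²) = 16 (a substantial fraction with 2N·s_e > 4, where
transient changes in second and third moments of the phenotype distribution
matter).

### Calibration

The expected equilibrium overall genic variance is
V_{A,O} = 2NU ∫ v(a) g(a) da with v(a) = 4a·D₊(a/2) (D₊ the Dawson
function), integrated by adaptive quadrature on the exponential scale
(relative tolerance 1e−10, scale-free substitution u = a²/E(a²) so very
small and very large E(a²) are handled equally well). The integral is
linear in U, so calibrating U to a target variance is an exact inversion:
at N = 1000, V_S = 2N, target V_{A,*} = 40, it gives U = 0.013435 for
E(a²) = 1 and U = 0.004725 for E(a²) = 16.

## Analytic predictions

**Equilibrium moments.** V_{A,f}, V_{A,m} and the intersex covariance B are
angle integrals of h(φ) scaled by V_{A,O}; r_fm = B/√(V_{A,f}V_{A,m})
depends only on h(φ), hence is independent of the optima and of the
(signed) dimorphism at equilibrium.

**Drift-generated dimorphism.** With coinciding optima and r_fm < 1, the
sex-specific means fluctuate around the optima with stationary moments
V[z̄] = δ², V[z̄_{f/m}] = 2δ², Cov[z̄_f, z̄_m] = 0, so
V[SD±] = 4δ²; since SD± is close to Gaussian,
E[SD] = 2·√(2/π)·δ ≈ 1.6δ. Whether that matters for a given trait is read
off the unitless ratio E[SD]/√V_A (≈0.8 at V_A = 4δ², ≈0.53 at 9δ²).

**Response to optimum shifts.** In average/half-difference coordinates
(k_a = (k_f+k_m)/2, k_d = (k_f−k_m)/2), the expected change of the
distances follows the two-sex breeder's equation with a skew correction:

    E[Δ(D_a, D_d)] = −(1/2V_S) G′ (D_a, D_d)ᵀ + (1/2V_S)(μ₃,a, μ₃,d)ᵀ,
    G′ = [[V_{A,a}+B, V_{A,d}], [V_{A,d}, V_{A,a}−B]].

With constant moments, μ₃ = 0 and V_{A,d} = 0 this decouples into
exponentials with rates (V_{A,a} ± B)/(2V_S) (the Lande trajectories),
giving rapid-phase lengths t_a, t_d (time to decay to δ) with ratio
t_d/t_a = (1+r_fm)/(1−r_fm), and
SD±(t) = 2Λ_d(1 − e^{−t·V_{A,a}(1−r_fm)/(2V_S)}), exposed relative to the
pre-shift dimorphism so convergent shifts (Λ_d < 0) use the same formula.
Fixed backgrounds equilibrate much more slowly:
F_a(t) ≈ Λ_a e^{−t/2N}, and likewise F_d at low r_fm (the F_d
approximation degrades as r_fm → 1).

For multigenic architectures the moment-driven equation is integrated
numerically along a *simulated* moment series (linear interpolation between
recorded generations). We integrate each replicate's own moment series and
average the predicted trajectories: integrating the across-replicate mean
series instead discards the within-replicate correlation between the
moments and the distances and systematically undershoots the simulated
mean D_d.

## Numerical choices

- The closed-form Lande curves use continuous-time exponentials; the
  one-generation recursion they approximate has the exact discrete solution
  (1 − rate)^t, and the two differ by O(rate) per e-fold (≈1% at the
  default rates). Oracle tests compare the recursion against its discrete
  closed form at 1e−10.
- x + E[Δx] is clamped to [0, 1] before binomial sampling, guarding
  against rare overshoot for large-effect alleles.
- Fixation bookkeeping: an allele sampled at frequency 1 adds 2a_f (2a_m)
  to the fixed backgrounds and is dropped; at 0 it is dropped. The mean
  identity above is conserved exactly across these events.
- A state with no segregating variation has all moments 0 and r_fm
  undefined (reported as NaN, not 0); the same applies when one sex carries
  no variance.
- Replicate i of a run with master seed s uses the independent child
  stream SeedSequence(s, spawn_key=(i,)); runs are bit-reproducible given
  (seed, replicate index).
- Crossing times of recorded trajectories (e.g. time to 80% of the final
  dimorphism) use linear interpolation between recorded generations and are
  reported as censored (NaN) when the horizon does not span the target.

## Stationary-moment estimation

Stationary fluctuation moments are estimated from post-burn-in samples
thinned every N/10 generations, pooled over time and replicates, taking
second moments about the *known* optima (the stationary means); with
strongly autocorrelated series this avoids the downward bias of centering
on the sample mean. Aggregation across replicates reports 95% CIs as
1.96·SEM, with E[SD] computed from per-replicate |SD±| (absolute value
before averaging).

## Default study conditions

N = 1000, γ_f = γ_m = 1/√2, V_S = 2N, burn-in 10N generations for
V_{A,*} = 40 (100N for V_{A,*} = 9, 500N for V_{A,*} = 4 — lower-variance
traits equilibrate more slowly relative to drift), shifts of
{0.15, 0.25, 0.5}·√V_S (equal to 1.06, 1.77, 3.54 phenotypic SDs at
V_{A,*} = 40), shared fractions r ∈ {0.5, 0.8, 0.95}. Scenario runs default
to 25 replicates (8 with long time-averaging for equilibrium scenarios)
with CI widths always reported; these are scaled-down desk defaults — a
production-scale run (hundreds to thousands of replicates) uses the same
code paths with `replicates` overridden.

## What the simulator does and does not emulate

The simulator is the model's own Wright–Fisher Hardy–Weinberg scheme: one
sex-averaged frequency per allele, linkage equilibrium, selection through
the first-moment formula, no individuals. Tests passing therefore validate
the analytic predictions *within this scheme*; they do not probe linkage
disequilibrium, sex-specific allele-frequency divergence under strong
antagonistic selection, mate choice, overlapping generations, evolving
genetic architecture (modifier loci), or environmental variance (absorbed
into V_S). These are deliberate non-goals.

## Known limitations

- The drift-dimorphism closed forms assume the *sex-specific* variance
  component is itself highly polygenic. With V_{A,*} = 9, E(a²) = 1 and
  r = 0.8 the sex-specific mutational input is 2NU(1−r) ≈ 1.2 per
  generation and the measured V[SD±] falls ~15% below 4δ² (E[SD] ~8% below
  1.6δ); at V_{A,*} = 40 (input ≈ 5.4) the predictions are recovered. The
  equilibrium checks therefore pair r = 0.5 with V_{A,*} = 9 and r = 0.8
  with V_{A,*} = 40.
- Even at E(a²) = 1 a small positive μ₃,d builds up during discordant
  adaptation and decelerates the late decay of D_d relative to the constant-
  moment exponential; the closed form is accurate over the rapid phase, and
  the moment-driven integration tracks the full trajectory.
- E[r_fm] = r holds for the ratio of expectations; the time average of the
  per-generation ratio estimate is biased slightly low when few alleles
  segregate (noticeable below ~100 segregating alleles).
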
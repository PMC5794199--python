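# Methods

## Model structure and assumptions

The model deliberately collapses speech production and perception onto a
single one-dimensional axis shared by motor, auditory, and somatosensory
spaces. This is adequate for the phenomenon simulated — perturbation and
categorization along one formant-like continuum spanning /i/–/ɛ/–/a/ —
and it makes every inference available in closed or near-closed form.
Units are inter-phoneme distances ($D$); vowel centers sit at 0, 1, 2, and a
perturbation toward /a/ is positive. These numeric conventions are a
package choice: only ratios of distances to standard deviations matter, so
any affine re-labeling of the axis gives the same dimensionless results.

Knowledge is factored into four components: two sensorimotor forward maps
($\rho_A$, $\rho_S$) and two sets of per-vowel Gaussian sensory
characterizations. Priors over motor commands and vowels are uniform and
carry no parameters. The forward maps are treated as infinitely precise
(deterministic), so they enter the inferences by exact substitution — a
change of variables — never by a narrow-Gaussian approximation. Production
fuses the active sensory constraints as a product of Gaussians evaluated at
the mapped motor command; perception renormalizes per-vowel joint densities
over the three vowels. Only stable states before and after adaptation are
modeled; trial-to-trial learning dynamics are out of scope.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| `spacing` | 1 | D | inter-phoneme distance; sets the scale |
| `sigma_frac` | 1/8 | — | characterization sd / spacing, both modalities |
| `Perturbation.delta` | +0.4 | D | auditory feedback shift, + toward /a/ |
| `update_magnitude` | 1.0 | fraction of δ | how much of δ the forward map learns |
| `aud_char_sigma` | off | D | target σ of /ɛ/'s auditory characterization |
| `som_char_shift` | off | D | shift of /ɛ/'s somatosensory mean |
| `LocalWindow` | [0.6, 1.0], ramp 0.45 | D | where the local update applies |
| `AxisGrid` | [−1, 3], 2001 pts | D | numerical support |

The sd of 1/8 D gives eight standard deviations between neighboring vowel
centers: categories barely overlap, and categorization curves are sharp
sigmoids. The 0.4 D perturbation magnitude matches the reference
experimental protocol (40% of the inter-phoneme distance).

## Numerical choices

- **Log-space densities.** With categories 8 sd apart, linear-space products
  of Gaussian densities underflow; all densities are accumulated as log
  densities and exponentiated after subtracting the maximum
  (perception renormalizes with `logsumexp`), so the categorization curves
  never produce NaN even far into the tails.
- **Grid and quadrature.** Posteriors are normalized by the trapezoid rule
  on a uniform grid, default [−1, 3] with 2001 points (half-millimeter
  resolution in D/1000 terms). At this resolution the production-posterior
  mean agrees with the Gaussian-product closed form to better than 1e-6 D
  and boundary locations are accurate to better than 5e-4 D. A posterior
  whose mass reaches the grid edges (more than 1e-6 in the outermost cells)
  raises a support error rather than silently truncating.
- **Boundaries.** A category boundary is the 0.5 crossing of the tracked
  vowel's posterior curve, linearly interpolated within the bracketing grid
  cell. The crossing sits at the inflection of a near-logistic curve, where
  linear interpolation is most accurate. When a curve crosses 0.5 more than
  once (the middle vowel has a boundary on each side; local updates can in
  principle create wiggles), the crossing nearest a caller-supplied
  reference — the pre-adaptation boundary in the scenario pipeline — is
  used.
- **Summaries.** Compensation uses the posterior *mean* (identical to the
  mode in the affine cases, well defined for the skewed posteriors produced
  by local updates); the mode is reported alongside.
- **Mappings.** Forward maps are strictly increasing piecewise-linear
  functions with slope-1 extrapolation. This family is closed under the
  general update (a uniform shift), expresses the local update exactly, and
  has an exact segment-wise inverse (swap breakpoints and values). Strict
  monotonicity is enforced at construction, so every mapping in the package
  is invertible by audit.

## Design decisions in the adaptation updates

**Local update window.** The local update adds $s = \text{magnitude}\cdot
\delta$ to $\rho_A$ on a core interval with linear ramps back to identity.
The core defaults to the motor interval explored while compensating,
$[\mu_\varepsilon - |\delta|,\ \mu_\varepsilon] = [0.6, 1.0]$ for the
reference perturbation. The ramp width defaults to $1.125\,|\delta| = 0.45$:
it must exceed $|s|$ to keep the map strictly increasing (the descending
ramp has slope $1 - s/\text{ramp}$), and it must be narrow enough that the
distorted region of *auditory* space — $[1.0 + s,\ 1.45]$ on the /a/ side —
stays below the /ɛ-a/ boundary at 1.5. A wider ramp (e.g. 0.6) would drag
the /ɛ-a/ boundary along with the /i-ɛ/ one and destroy the one-sided shift
the local hypothesis exists to produce; the window is fully configurable
for exploring that regime.

**μ–σ coupling of the auditory characterization update.** The
shift-and-narrow update of /ɛ/'s auditory characterization ties the mean to
the sd so that the auditory-only /ɛ-a/ boundary is invariant: solving the
equal-density condition $\mathcal N(b_0;\mu,\sigma) = \mathcal
N(b_0;\mu_a,\sigma_a)$ for $\mu$ on /ɛ/'s side of the normal boundary
$b_0$ gives

$$\mu(\sigma) = b_0 - \sigma\sqrt{2\left(B + \ln\tfrac{\sigma_a}{\sigma}\right)},
\qquad B = \frac{(b_0-\mu_a)^2}{2\sigma_a^2},$$

with $\mu(\sigma_0) = \mu_\varepsilon$ exactly at the normal sd. This is
the unique smooth (μ, σ) family that pins that boundary; no claim of
cognitive plausibility attaches to it — it encodes the *behavioral*
constraint that the boundary on the perturbed side does not move. For
$\sigma = \sigma_0/2$ the implied mean shift is ≈ 0.2394 D toward /a/.

**Somatosensory characterization update.** When enabled, the default
magnitude in the canned scenario suite equals the compensation displacement
of the full local update under equal precision (0.2 D toward /i/),
reflecting the new articulatory posture; the value is configurable.

**Update composition.** The three updates touch disjoint state components
(the auditory-motor map; /ɛ/'s auditory Gaussian; /ɛ/'s somatosensory
Gaussian), so combined hypotheses commute bit-exactly; this is asserted in
the tests rather than assumed.

## The sweep protocol

Inter-subject variability is modeled as explicit parameter sweeps — the
package contains no random number generation anywhere. Internal-model
update magnitudes take six values {0, 0.2, …, 1.0}; the auditory narrowing
takes six σ values evenly spaced from σ₀ down to σ₀/2 (means follow the
μ–σ coupling); somatosensory sds take {1/8, 1/6, 1/4} D, applied to all
three vowels, keeping σ_S ≥ σ_A (auditory-dominant subjects). For each
perception/adaptation combination the compensation and the /i-ɛ/-side
perceptual shift are correlated across the swept points with Pearson's r
(Spearman available by configuration; which coefficient the reference
analyses used is not stated, so the choice is exposed). Zero-variance
sweeps yield an explicit undefined flag rather than an error.

## What the simulations do and do not show

The sweeps emulate deterministic idealized subjects that differ only along
the swept parameters; they contain no measurement noise, no trial-level
variability, no response bias in the perceptual test, and no nonlinearity
in the sensorimotor maps beyond the piecewise-linear local update. Passing
tests therefore demonstrate the *internal* consistency of the hypotheses —
directions, asymmetries, and correlation signs that each knowledge update
can or cannot produce — not quantitative agreement with any particular
subject pool. The magnitude of the one-sided boundary shift in particular
is sensitive to the local-update window and the μ–σ coupling, which is
itself a finding: asymmetry claims are fragile to these parameters.

## Known limitations

- One-dimensional, piecewise-linear sensorimotor maps: no motor
  equivalence, no many-to-one mappings.
- Stable-state comparison only; nothing is said about the time course of
  learning or washout.
- The somatosensory-motor map is never updated (the perturbation leaves the
  motor-to-somatosensory relation intact by construction).
- Production always fuses both pathways; single-pathway production
  questions are implemented and tested but carry no experiment harness.
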
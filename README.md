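# speechadapt

Deterministic Bayesian simulation of speech motor adaptation to altered
auditory feedback, and of its consequences for phoneme categorization.

## The scientific problem

When speakers hear their own vowel productions shifted along a formant-like
continuum (e.g. /ɛ/ pushed toward /a/), they adapt their articulation to
oppose the shift — but never completely — and their perceptual category
boundaries move as well, usually in the direction of the perturbation and
only on one side of the perturbed vowel. `speechadapt` implements a
one-dimensional Bayesian model of this phenomenon for researchers in speech
motor control and perceptuo-motor interaction, letting them state competing
hypotheses about *which* stored knowledge adaptation changes and simulate
the behavioral signature of each.

## The model

All spaces — motor commands $M$, auditory values $A$, somatosensory values
$S$ — share one axis whose unit is the inter-phoneme distance $D$. The
agent's knowledge comprises:

- deterministic internal forward models $\rho_A$ (motor→auditory) and
  $\rho_S$ (motor→somatosensory), strictly increasing piecewise-linear maps,
  both the identity before adaptation;
- Gaussian characterizations of each vowel /i/, /ɛ/, /a/ in auditory and
  somatosensory terms, $\mathcal N(\mu_{A\phi},\sigma_{A\phi}^2)$ and
  $\mathcal N(\mu_{S\phi},\sigma_{S\phi}^2)$, with means $0, 1, 2$ and
  common sd $1/8\,D$ before adaptation.

Production plans motor commands for a target vowel $\phi$ by fusing both
sensory constraints,

$$P(m \mid \phi) \propto \mathcal N(\rho_A(m);\, \mu_{A\phi}, \sigma_{A\phi}^2)\;
\mathcal N(\rho_S(m);\, \mu_{S\phi}, \sigma_{S\phi}^2),$$

and perception categorizes an auditory stimulus $a$ either through the
auditory pathway alone (a softmax of Gaussian exponents over the three
vowels) or through the fusion of pathways, where the somatosensory term is
evaluated at the somatosensory image $\rho_S(\rho_A^{-1}(a))$.

Adaptation to a perturbation $\delta$ ($+0.4\,D$ toward /a/ in the reference
protocol) is modeled as a stable-state update of one or more knowledge
components: a *general* or *local* update of $\rho_A$ by $\delta$
(hypothesis HAdM), a coordinated shift-and-narrowing of the auditory
characterization of /ɛ/ that leaves the /ɛ-a/ auditory boundary fixed
(HAdΦ), a shift of the somatosensory characterization of /ɛ/, or any
combination (e.g. HAdMΦ). Scenario metrics are the **compensation fraction**
(production displacement in units of $\delta$, opposite direction positive)
and **perceptual boundary shifts** (displacement of the 0.5 crossing of a
categorization curve, per side of /ɛ/, in units of $\delta$). Sweeping
update magnitudes, narrowing levels, and relative sensory precisions
simulates inter-subject variability and yields the correlation between
compensation and perceptual shift under each hypothesis combination.

## Worked example

```python
from speechadapt import AdaptationSpec, Perturbation, run_scenario

pert = Perturbation(delta=0.4)           # +40% of the /ɛ/-/a/ distance
spec = AdaptationSpec(internal_model="local", update_magnitude=1.0)
res = run_scenario(spec, pert)

print(f"compensation: {100 * res.compensation_fraction:.1f}% of the perturbation")
print(f"QPerF /i-ɛ/ boundary shift: {res.boundary_shift('QPerF', 'i_eh'):+.3f} (units of delta)")
print(f"QPerF /ɛ-a/ boundary shift: {res.boundary_shift('QPerF', 'eh_ah'):+.3f}")
print(f"QPerA boundary shifts:      {res.boundary_shift('QPerA', 'i_eh'):+.3f}, "
      f"{res.boundary_shift('QPerA', 'eh_ah'):+.3f}")
```

prints

```
compensation: 47.7% of the perturbation
QPerF /i-ɛ/ boundary shift: +0.269 (units of delta)
QPerF /ɛ-a/ boundary shift: +0.000
QPerA boundary shifts:      +0.000, +0.000
```

Even though the internal model learned the full perturbation, compensation
stops near 48%: planning compromises between the auditory target (which the
updated map now places at a fronted articulation) and the unchanged
somatosensory target. Under fusion-based perception the /i-ɛ/ boundary moves
with the perturbation by $0.269\,\delta \approx 0.11\,D$ while the /ɛ-a/
boundary does not move — the one-sided shift — and auditory-only perception
is untouched by an internal-model update.

The same protocol is available from a shell:

```sh
echo '{}' > scenario.yaml                      # empty file = reference protocol
speechadapt simulate scenario.yaml --out result.json
speechadapt curves   scenario.yaml --out curves.csv
speechadapt correlate scenario.yaml --out sweep.csv
```

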
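"""Knowledge updates implementing the adaptation hypotheses.

After training against a shifted auditory feedback, three disjoint pieces of
knowledge may have changed:

* the auditory-motor forward map (``HAdM``) — either a *general* update that
  shifts the whole map by the learned offset, or a *local* update confined to
  the motor interval explored while compensating (plateau of full update with
  linear ramps back to identity);
* the auditory characterization of the perturbed vowel (``HAdPhi``) — a
  coordinated shift of its mean toward the perturbation and narrowing of its
  standard deviation, tied together so that the auditory-only boundary on the
  perturbed side does not move;
* the somatosensory characterization of the perturbed vowel — a mean shift
  toward the compensatory articulation (opposite to the perturbation).

The three updates touch disjoint components of the model state, so any
combination of them commutes bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigurationError
from .model import (
    GaussianCharacterization,
    ModelState,
    MonotoneMapping,
    Phoneme,
)

__all__ = [
    "Perturbation",
    "LocalWindow",
    "AdaptationSpec",
    "MuSigmaRelation",
    "apply_general_update",
    "apply_local_update",
    "mu_from_sigma",
    "apply_auditory_char_update",
    "apply_somato_char_update",
    "build_adapted_state",
]

#: Default ramp width as a multiple of |delta|.  Wider than the largest
#: possible update (monotonicity needs ramp > magnitude*|delta|) yet narrow
#: enough that the distorted auditory region stays between the perturbed
#: vowel and its unperturbed neighbour, keeping the far-side boundary fixed.
_DEFAULT_RAMP_FACTOR = 1.125


@dataclass(frozen=True)
class Perturbation:
    """Signed auditory feedback shift applied while the subject speaks.

    ``delta`` is in D units; positive means toward /a/.  The protocol
    perturbs the middle vowel /ɛ/.
    """

    delta: float = 0.4
    target: Phoneme = Phoneme.EH

    def __post_init__(self) -> None:
        if not abs(self.delta) < 1.0:
            raise ConfigurationError(
                f"|delta| must stay within the inter-phoneme gap (< 1 D), got {self.delta}"
            )


@dataclass(frozen=True)
class LocalWindow:
    """Motor-axis window of a local internal-model update.

    The update has full weight on [core_lo, core_hi] and falls linearly to
    zero over ``ramp`` on each side.
    """

    core_lo: float
    core_hi: float
    ramp: float

    def __post_init__(self) -> None:
        if not self.core_lo < self.core_hi:
            raise ConfigurationError("local window requires core_lo < core_hi")
        if not self.ramp > 0:
            raise ConfigurationError("local window ramp must be > 0")

    @classmethod
    def default(cls, pert: Perturbation, center: float = 1.0) -> "LocalWindow":
        """Window over the motor interval explored during compensation.

        Compensation moves production from ``center`` opposite to the
        perturbation by up to |delta|, so the core spans that interval.
        """
        d = abs(pert.delta)
        if pert.delta > 0:
            lo, hi = center - d, center
        else:
            lo, hi = center, center + d
        return cls(core_lo=lo, core_hi=hi, ramp=_DEFAULT_RAMP_FACTOR * d)


@dataclass(frozen=True)
class AdaptationSpec:
    """Which updates an adaptation scenario applies, and how strongly.

    Parameters
    ----------
    internal_model : {"none", "general", "local"}
        Kind of auditory-motor map update.
    update_magnitude : float in [0, 1]
        Fraction of the perturbation learned by the internal model.
    aud_char_sigma : float or None
        Target sd of the perturbed vowel's auditory characterization; the
        mean shift follows from the boundary-invariance relation.  None
        disables the update.
    som_char_shift : float or None
        Signed shift of the perturbed vowel's somatosensory mean (negative =
        toward /i/ under the sign convention).  None disables the update.
    local_window : LocalWindow or None
        Window for the local update; None selects the default window.
    """

    internal_model: str = "none"
    update_magnitude: float = 1.0
    aud_char_sigma: Optional[float] = None
    som_char_shift: Optional[float] = None
    local_window: Optional[LocalWindow] = None

    def __post_init__(self) -> None:
        if self.internal_model not in ("none", "general", "local"):
            raise ConfigurationError(
                f"internal_model must be 'none', 'general' or 'local', "
                f"got {self.internal_model!r}"
            )
        if not 0.0 <= self.update_magnitude <= 1.0:
            raise ConfigurationError(
                f"update_magnitude must be in [0, 1], got {self.update_magnitude}"
            )
        if self.aud_char_sigma is not None and not self.aud_char_sigma > 0:
            raise ConfigurationError(
                f"aud_char_sigma must be > 0, got {self.aud_char_sigma}"
            )


def apply_general_update(
    state: ModelState, pert: Perturbation, magnitude: float
) -> ModelState:
    """Shift the whole auditory-motor map by ``magnitude * delta``.

    Everything else — the somatosensory-motor map and all characterizations —
    is untouched.  ``magnitude = 0`` returns the state unchanged bit-exactly.
    """
    if magnitude == 0.0:
        return state
    return state.replace(rho_A=state.rho_A.shifted(magnitude * pert.delta))


def apply_local_update(
    state: ModelState,
    pert: Perturbation,
    magnitude: float,
    window: Optional[LocalWindow] = None,
) -> ModelState:
    """Add ``magnitude * delta`` to the auditory-motor map inside a window.

    The new map is rho_A(m) + s*w(m) with s = magnitude*delta and w a
    trapezoidal weight: 1 on the core, linear ramps of width ``window.ramp``
    down to 0, 0 outside.  Strict monotonicity requires ramp > |s|.
    """
    if magnitude == 0.0:
        return state
    if window is None:
        center = float(state.rho_A.inverse()(state.aud_chars[pert.target].mean))
        window = LocalWindow.default(pert, center=center)
    s = magnitude * pert.delta
    if not window.ramp > abs(s):
        raise ConfigurationError(
            f"ramp width {window.ramp} must exceed |update| {abs(s)} "
            "to preserve monotonicity"
        )
    kinks = np.array(
        [
            window.core_lo - window.ramp,
            window.core_lo,
            window.core_hi,
            window.core_hi + window.ramp,
        ]
    )
    bp = np.union1d(state.rho_A.breakpoints, kinks)
    w = np.clip(
        np.minimum(
            (bp - (window.core_lo - window.ramp)) / window.ramp,
            ((window.core_hi + window.ramp) - bp) / window.ramp,
        ),
        0.0,
        1.0,
    )
    values = state.rho_A(bp) + s * w
    return state.replace(rho_A=MonotoneMapping(bp, values))


@dataclass(frozen=True)
class MuSigmaRelation:
    """Coupling between the perturbed vowel's auditory mean and sd.

    Designed so that as the characterization narrows (sd decreases from its
    normal value) its mean slides toward the unperturbed neighbour exactly
    fast enough to keep the auditory-only boundary on that side fixed at the
    normal boundary ``b0``.  At sd = normal sd the shift is zero.
    """

    b0: float
    neighbor: GaussianCharacterization
    target_normal: GaussianCharacterization

    @classmethod
    def from_state(
        cls,
        state: ModelState,
        target: Phoneme = Phoneme.EH,
        neighbor: Phoneme = Phoneme.AH,
    ) -> "MuSigmaRelation":
        t = state.aud_chars[target]
        nb = state.aud_chars[neighbor]
        if t.sd != nb.sd:
            raise ConfigurationError(
                "mu-sigma relation is derived from a normal state with equal "
                f"auditory sds; got {t.sd} vs {nb.sd}"
            )
        return cls(b0=0.5 * (t.mean + nb.mean), neighbor=nb, target_normal=t)


def mu_from_sigma(rel: MuSigmaRelation, sigma: float) -> float:
    """Mean shift paired with a target sd so the far-side boundary is fixed.

    Solving the equal-density condition N(b0; mu, sigma) = N(b0; mu_n, sd_n)
    for the mean on the target's side of ``b0`` gives

        mu = b0 - sign(mu_n - mu_t) * sigma * sqrt(2*(B + ln(sd_n/sigma))),
        B  = (b0 - mu_n)^2 / (2*sd_n^2),

    and the returned shift is mu - mu_normal (>= 0, toward the neighbour,
    for sigma <= normal sd; zero at sigma = normal sd).
    """
    sd0 = rel.target_normal.sd
    if not 0.0 < sigma <= sd0:
        raise ConfigurationError(
            f"sigma must be in (0, {sd0}] (normal sd), got {sigma}"
        )
    nb = rel.neighbor
    b = (rel.b0 - nb.mean) ** 2 / (2.0 * nb.sd**2)
    direction = math.copysign(1.0, nb.mean - rel.target_normal.mean)
    mu_new = rel.b0 - direction * sigma * math.sqrt(2.0 * (b + math.log(nb.sd / sigma)))
    return mu_new - rel.target_normal.mean


def apply_auditory_char_update(
    state: ModelState,
    sigma: float,
    rel: Optional[MuSigmaRelation] = None,
    target: Phoneme = Phoneme.EH,
) -> ModelState:
    """Shift-and-narrow the perturbed vowel's auditory characterization.

    Only P(A_phi | phi = target) changes: its sd becomes ``sigma`` and its
    mean moves by the boundary-preserving shift.  ``sigma`` equal to the
    normal sd leaves the state unchanged bit-exactly.
    """
    if rel is None:
        rel = MuSigmaRelation.from_state(state, target=target)
    if sigma == rel.target_normal.sd:
        return state
    shift = mu_from_sigma(rel, sigma)
    new_chars = dict(state.aud_chars)
    new_chars[target] = GaussianCharacterization(
        rel.target_normal.mean + shift, sigma
    )
    return state.replace(aud_chars=new_chars)


def apply_somato_char_update(
    state: ModelState, shift: float, target: Phoneme = Phoneme.EH
) -> ModelState:
    """Shift the perturbed vowel's somatosensory mean by ``shift``.

    Negative values move it toward /i/, the direction of the compensatory
    articulation for a perturbation toward /a/.
    """
    if shift == 0.0:
        return state
    old = state.som_chars[target]
    new_chars = dict(state.som_chars)
    new_chars[target] = GaussianCharacterization(old.mean + shift, old.sd)
    return state.replace(som_chars=new_chars)


def build_adapted_state(
    normal: ModelState, spec: AdaptationSpec, pert: Perturbation
) -> ModelState:
    """Apply the configured updates to a normal-condition state.

    Application order is immaterial: the internal-model update touches only
    the auditory-motor map, the auditory characterization update only the
    perturbed vowel's auditory Gaussian, and the somatosensory update only
    its somatosensory Gaussian.
    """
    state = normal
    if spec.internal_model == "general":
        state = apply_general_update(state, pert, spec.update_magnitude)
    elif spec.internal_model == "local":
        state = apply_local_update(state, pert, spec.update_magnitude, spec.local_window)
    if spec.aud_char_sigma is not None:
        # the boundary held fixed is the one on the perturbed side
        neighbor = Phoneme.AH if pert.delta > 0 else Phoneme.I
        rel = MuSigmaRelation.from_state(normal, target=pert.target, neighbor=neighbor)
        state = apply_auditory_char_update(
            state, spec.aud_char_sigma, rel=rel, target=pert.target
        )
    if spec.som_char_shift is not None:
        state = apply_somato_char_update(state, spec.som_char_shift, target=pert.target)
    return state
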
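"""Model state: phonemes, Gaussian characterizations, and sensorimotor maps.

The agent's knowledge lives on a single shared one-dimensional axis for motor,
auditory, and somatosensory spaces.  The unit of the axis is the inter-phoneme
distance D; phoneme centers default to /i/ = 0, /ɛ/ = 1, /a/ = 2, and a
perturbation toward /a/ is positive.  Knowledge has four components:

* two deterministic sensorimotor forward maps, motor→auditory (``rho_A``) and
  motor→somatosensory (``rho_S``), represented as strictly increasing
  piecewise-linear functions with exact inverses;
* Gaussian auditory and somatosensory characterizations of each phoneme.

Priors over motor commands and phonemes are uniform by construction and carry
no stored parameters.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping

import numpy as np
from scipy.stats import norm

from .errors import ConfigurationError, MonotonicityError

__all__ = [
    "Phoneme",
    "PHONEMES",
    "GaussianCharacterization",
    "MonotoneMapping",
    "ModelState",
    "AxisGrid",
    "PathwayConfig",
    "AUDITORY",
    "SOMATOSENSORY",
    "FUSION",
    "default_grid",
    "build_normal_state",
    "mapping_eval",
    "mapping_inverse",
    "somato_image",
]


class Phoneme(enum.Enum):
    """The three vowels, ordered /i/ < /ɛ/ < /a/ along the shared axis."""

    I = "i"
    EH = "eh"
    AH = "ah"

    def __repr__(self) -> str:  # keeps scenario dumps compact
        return f"Phoneme.{self.name}"


#: Canonical axis order of the three phonemes.
PHONEMES = (Phoneme.I, Phoneme.EH, Phoneme.AH)

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class GaussianCharacterization:
    """Gaussian sensory characterization of a phoneme: N(mean, sd^2)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ConfigurationError(f"sd must be > 0, got {self.sd}")

    def logpdf(self, x):
        """Log density at ``x`` (scalar or array), evaluated in log space."""
        z = (np.asarray(x, dtype=float) - self.mean) / self.sd
        return -0.5 * z * z - np.log(self.sd) - _LOG_SQRT_2PI

    def pdf(self, x):
        return norm.pdf(x, loc=self.mean, scale=self.sd)


class MonotoneMapping:
    """Strictly increasing piecewise-linear map with slope-1 extrapolation.

    Exact for the affine sensorimotor maps of the normal condition and for the
    general internal-model update, and expressive enough for the local
    (plateau + ramp) update.  Strict monotonicity is enforced at construction,
    which makes the inverse another :class:`MonotoneMapping` obtained by
    swapping breakpoints and values (slope-1 extrapolation is self-inverse).
    """

    __slots__ = ("breakpoints", "values")

    def __init__(self, breakpoints, values) -> None:
        bp = np.array(breakpoints, dtype=float)
        v = np.array(values, dtype=float)
        if bp.ndim != 1 or bp.shape != v.shape or bp.size < 2:
            raise ConfigurationError(
                "breakpoints and values must be 1-D arrays of equal length >= 2"
            )
        if not np.all(np.diff(bp) > 0):
            raise MonotonicityError("breakpoints must be strictly increasing")
        if not np.all(np.diff(v) > 0):
            raise MonotonicityError(
                "mapping values must be strictly increasing (invertibility)"
            )
        bp.setflags(write=False)
        v.setflags(write=False)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "values", v)

    def __setattr__(self, name, value):  # immutability guard
        raise AttributeError("MonotoneMapping is immutable")

    @classmethod
    def identity(cls) -> "MonotoneMapping":
        """The exact identity map (two breakpoints suffice)."""
        return cls([0.0, 1.0], [0.0, 1.0])

    def shifted(self, delta: float) -> "MonotoneMapping":
        """Return the map x -> self(x) + delta."""
        return MonotoneMapping(self.breakpoints, self.values + float(delta))

    def __call__(self, x):
        xs = np.asarray(x, dtype=float)
        y = np.interp(xs, self.breakpoints, self.values)
        lo, hi = self.breakpoints[0], self.breakpoints[-1]
        y = np.where(xs < lo, self.values[0] + (xs - lo), y)
        y = np.where(xs > hi, self.values[-1] + (xs - hi), y)
        return float(y) if np.isscalar(x) or xs.ndim == 0 else y

    def inverse(self) -> "MonotoneMapping":
        """Exact inverse map (segment-wise)."""
        return MonotoneMapping(self.values, self.breakpoints)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MonotoneMapping):
            return NotImplemented
        return np.array_equal(self.breakpoints, other.breakpoints) and np.array_equal(
            self.values, other.values
        )

    def __hash__(self):
        return hash((self.breakpoints.tobytes(), self.values.tobytes()))

    def __repr__(self) -> str:
        return (
            f"MonotoneMapping(breakpoints={self.breakpoints.tolist()}, "
            f"values={self.values.tolist()})"
        )

    def to_dict(self) -> dict:
        return {
            "breakpoints": self.breakpoints.tolist(),
            "values": self.values.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MonotoneMapping":
        return cls(d["breakpoints"], d["values"])


@dataclass(frozen=True)
class AxisGrid:
    """Uniform numerical support for the continuous motor/auditory axis."""

    lo: float = -1.0
    hi: float = 3.0
    n: int = 2001

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ConfigurationError(f"grid needs n >= 3 points, got {self.n}")
        if not self.lo < self.hi:
            raise ConfigurationError(f"grid bounds require lo < hi, got {self.lo} >= {self.hi}")

    @property
    def spacing(self) -> float:
        return (self.hi - self.lo) / (self.n - 1)

    def points(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n)

    def to_dict(self) -> dict:
        return {"lo": self.lo, "hi": self.hi, "n": self.n}

    @classmethod
    def from_dict(cls, d: Mapping) -> "AxisGrid":
        return cls(float(d["lo"]), float(d["hi"]), int(d["n"]))


def default_grid() -> AxisGrid:
    """Default axis support [-1, 3] with 2001 points.

    Covers all phoneme means ± at least 8 sd in the normal condition and
    locates categorization boundaries to better than 5e-4 D.
    """
    return AxisGrid(-1.0, 3.0, 2001)


@dataclass(frozen=True)
class PathwayConfig:
    """Which sensory pathways constrain an inference (coherence switches).

    ``use_auditory`` closes the auditory matching constraint, and
    ``use_somatosensory`` the somatosensory one.  Both open would disconnect
    phonemes from motor commands entirely, so at least one must be set.
    """

    use_auditory: bool = True
    use_somatosensory: bool = True

    def __post_init__(self) -> None:
        if not (self.use_auditory or self.use_somatosensory):
            raise ConfigurationError("at least one sensory pathway must be active")


AUDITORY = PathwayConfig(use_auditory=True, use_somatosensory=False)
SOMATOSENSORY = PathwayConfig(use_auditory=False, use_somatosensory=True)
FUSION = PathwayConfig(use_auditory=True, use_somatosensory=True)


@dataclass(frozen=True)
class ModelState:
    """Complete agent knowledge: two forward maps + four×three Gaussians."""

    rho_A: MonotoneMapping
    rho_S: MonotoneMapping
    aud_chars: Dict[Phoneme, GaussianCharacterization] = field(default_factory=dict)
    som_chars: Dict[Phoneme, GaussianCharacterization] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, chars in (("aud_chars", self.aud_chars), ("som_chars", self.som_chars)):
            if set(chars) != set(PHONEMES):
                raise ConfigurationError(
                    f"{name} must characterize exactly the phonemes "
                    f"{[p.value for p in PHONEMES]}"
                )

    def replace(self, **changes) -> "ModelState":
        from dataclasses import replace as _replace

        return _replace(self, **changes)

    def to_dict(self) -> dict:
        return {
            "rho_A": self.rho_A.to_dict(),
            "rho_S": self.rho_S.to_dict(),
            "aud_chars": {
                p.value: {"mean": c.mean, "sd": c.sd} for p, c in self.aud_chars.items()
            },
            "som_chars": {
                p.value: {"mean": c.mean, "sd": c.sd} for p, c in self.som_chars.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelState":
        def chars(block):
            return {
                Phoneme(k): GaussianCharacterization(float(v["mean"]), float(v["sd"]))
                for k, v in block.items()
            }

        return cls(
            rho_A=MonotoneMapping.from_dict(d["rho_A"]),
            rho_S=MonotoneMapping.from_dict(d["rho_S"]),
            aud_chars=chars(d["aud_chars"]),
            som_chars=chars(d["som_chars"]),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "ModelState":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_normal_state(
    spacing: float = 1.0,
    sigma_frac: float = 0.125,
    centers: Mapping[Phoneme, float] | None = None,
) -> ModelState:
    """Construct the fully symmetric pre-adaptation model.

    Both forward maps are the exact identity; auditory and somatosensory
    characterizations coincide, with means evenly spaced by ``spacing`` and a
    common standard deviation ``sigma_frac * spacing`` (default 1/8 of the
    inter-phoneme distance).

    Parameters
    ----------
    spacing : float
        Inter-phoneme distance D (must be > 0).
    sigma_frac : float
        Characterization sd as a fraction of ``spacing`` (must be > 0).
    centers : mapping, optional
        Explicit per-phoneme positions; must be strictly increasing in the
        order /i/ < /ɛ/ < /a/.  Defaults to {0, spacing, 2*spacing}.
    """
    if not spacing > 0:
        raise ConfigurationError(f"spacing must be > 0, got {spacing}")
    if not sigma_frac > 0:
        raise ConfigurationError(f"sigma_frac must be > 0, got {sigma_frac}")
    if centers is None:
        centers = {p: i * spacing for i, p in enumerate(PHONEMES)}
    else:
        centers = dict(centers)
        if set(centers) != set(PHONEMES):
            raise ConfigurationError("centers must provide a position for each phoneme")
        ordered = [centers[p] for p in PHONEMES]
        if not all(a < b for a, b in zip(ordered, ordered[1:])):
            raise ConfigurationError("centers must be strictly increasing /i/ < /ɛ/ < /a/")
    sd = sigma_frac * spacing
    chars = {p: GaussianCharacterization(float(centers[p]), sd) for p in PHONEMES}
    return ModelState(
        rho_A=MonotoneMapping.identity(),
        rho_S=MonotoneMapping.identity(),
        aud_chars=dict(chars),
        som_chars=dict(chars),
    )


def mapping_eval(mapping: MonotoneMapping, x):
    """Evaluate a mapping at ``x`` (piecewise-linear, slope-1 extrapolation)."""
    return mapping(x)


def mapping_inverse(mapping: MonotoneMapping, y):
    """Evaluate the exact inverse of a mapping at ``y``."""
    return mapping.inverse()(y)


def somato_image(state: ModelState, a):
    """Somatosensory image rho_S(rho_A^-1(a)) of an auditory value.

    This is the predicted somatosensory consequence of the motor command that
    the (possibly updated) auditory-motor map associates with hearing ``a``.
    """
    return state.rho_S(state.rho_A.inverse()(a))
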
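"""Production and perception questions computed from a model state.

Production infers a posterior over motor commands for a target phoneme; the
deterministic forward maps substitute exactly into the Gaussian
characterizations (change of variables, no narrow-Gaussian approximation), so

    P(m | phi, pathways)  propto  N(rho_A(m); mu_A, sd_A)^[aud] *
                                  N(rho_S(m); mu_S, sd_S)^[som]

normalized on the grid.  Perception categorizes an auditory stimulus ``a``
into a phoneme: the auditory term evaluates the auditory characterization at
``a`` itself, the somatosensory term evaluates the somatosensory
characterization at the somatosensory image rho_S(rho_A^-1(a)); the per-
phoneme product is renormalized over the three phonemes (a softmax of
Gaussian exponents).  All densities are accumulated in log space: with
characterizations eight standard deviations apart, linear-space products
underflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import BoundaryNotFoundError, SupportError
from .model import (
    FUSION,
    AxisGrid,
    ModelState,
    PathwayConfig,
    Phoneme,
    PHONEMES,
    default_grid,
    somato_image,
)

__all__ = [
    "ProductionPosterior",
    "CategorizationCurve",
    "Boundary",
    "production_posterior",
    "perception_posterior",
    "categorization_curve",
    "find_boundary",
]

#: Maximum tolerated posterior mass in the two outermost grid cells.
_EDGE_MASS_TOL = 1e-6


@dataclass(frozen=True)
class ProductionPosterior:
    """Normalized density over motor commands for one target phoneme."""

    grid: AxisGrid
    density: np.ndarray
    mean: float
    mode: float
    sd: float
    target: Phoneme
    pathways: PathwayConfig

    def summary(self) -> dict:
        return {"mean": self.mean, "mode": self.mode, "sd": self.sd}

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per grid point."""
        q = _question_label(self.pathways)
        return pd.DataFrame(
            {
                "question": q,
                "phoneme": self.target.value,
                "motor_command": self.grid.points(),
                "density": self.density,
            }
        )


@dataclass(frozen=True)
class CategorizationCurve:
    """Per-phoneme posterior probability along an auditory stimulus grid."""

    grid: AxisGrid
    probs: Dict[Phoneme, np.ndarray]
    pathways: PathwayConfig

    @property
    def question(self) -> str:
        return _question_label(self.pathways)

    def to_frame(self) -> pd.DataFrame:
        x = self.grid.points()
        frames = [
            pd.DataFrame(
                {
                    "question": self.question,
                    "phoneme": p.value,
                    "stimulus": x,
                    "probability": self.probs[p],
                }
            )
            for p in PHONEMES
        ]
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class Boundary:
    """Location of a 0.5 crossing of a categorization curve.

    ``slope`` is the finite-difference slope (probability per D) of the
    tracked phoneme's curve within the bracketing grid cell, useful for
    comparing the sharpness of categorization across questions.
    """

    pair: Tuple[Phoneme, Phoneme]
    location: float
    slope: float


def _question_label(pathways: PathwayConfig) -> str:
    if pathways.use_auditory and pathways.use_somatosensory:
        return "fusion"
    return "auditory" if pathways.use_auditory else "somatosensory"


def production_posterior(
    state: ModelState,
    target: Phoneme,
    pathways: PathwayConfig = FUSION,
    grid: Optional[AxisGrid] = None,
) -> ProductionPosterior:
    """Posterior over motor commands for producing ``target``.

    Raises
    ------
    SupportError
        If more than 1e-6 of the posterior mass falls in the outermost grid
        cells, i.e. the grid is too narrow to support the posterior.
    """
    grid = grid if grid is not None else default_grid()
    m = grid.points()
    logd = np.zeros_like(m)
    if pathways.use_auditory:
        logd = logd + state.aud_chars[target].logpdf(state.rho_A(m))
    if pathways.use_somatosensory:
        logd = logd + state.som_chars[target].logpdf(state.rho_S(m))
    d = np.exp(logd - logd.max())
    z = np.trapezoid(d, m)
    density = d / z
    h = grid.spacing
    edge_mass = 0.5 * h * (density[0] + density[1] + density[-2] + density[-1])
    if edge_mass > _EDGE_MASS_TOL:
        raise SupportError(
            f"posterior mass {edge_mass:.3g} at grid edges [{grid.lo}, {grid.hi}]; "
            "widen the grid"
        )
    mean = float(np.trapezoid(m * density, m))
    var = float(np.trapezoid((m - mean) ** 2 * density, m))
    mode = float(m[int(np.argmax(density))])
    return ProductionPosterior(
        grid=grid,
        density=density,
        mean=mean,
        mode=mode,
        sd=float(np.sqrt(var)),
        target=target,
        pathways=pathways,
    )


def perception_posterior(
    state: ModelState,
    a,
    pathways: PathwayConfig = FUSION,
) -> Dict[Phoneme, np.ndarray]:
    """Phoneme posterior for auditory stimulus ``a`` (scalar or array).

    With auditory-only pathways the result depends only on the auditory
    characterizations, so it is unaffected — bit for bit — by any change to
    the forward maps or to the somatosensory characterizations.
    """
    a_arr = np.atleast_1d(np.asarray(a, dtype=float))
    if pathways.use_somatosensory:
        s_img = somato_image(state, a_arr)
    logps = []
    for p in PHONEMES:
        lp = np.zeros_like(a_arr)
        if pathways.use_auditory:
            lp = lp + state.aud_chars[p].logpdf(a_arr)
        if pathways.use_somatosensory:
            lp = lp + state.som_chars[p].logpdf(s_img)
        logps.append(lp)
    stacked = np.vstack(logps)
    probs = np.exp(stacked - logsumexp(stacked, axis=0, keepdims=True))
    scalar = np.isscalar(a) or np.asarray(a).ndim == 0
    return {
        p: (float(probs[i, 0]) if scalar else probs[i])
        for i, p in enumerate(PHONEMES)
    }


def categorization_curve(
    state: ModelState,
    grid: Optional[AxisGrid] = None,
    pathways: PathwayConfig = FUSION,
) -> CategorizationCurve:
    """Perception posterior evaluated at every grid point."""
    grid = grid if grid is not None else default_grid()
    probs = perception_posterior(state, grid.points(), pathways)
    return CategorizationCurve(grid=grid, probs=probs, pathways=pathways)


def find_boundary(
    curve: CategorizationCurve,
    pair: Tuple[Phoneme, Phoneme],
    reference: Optional[float] = None,
) -> Boundary:
    """Locate the 0.5 crossing of ``pair[0]``'s curve for a phoneme pair.

    The crossing is linearly interpolated within the bracketing grid cell.
    If the curve crosses 0.5 more than once (e.g. the middle vowel's curve
    has a boundary on each side), the crossing nearest ``reference`` is
    returned; with multiple crossings and no reference the call is ambiguous
    and raises ``ValueError``.

    Raises
    ------
    BoundaryNotFoundError
        If the curve never crosses 0.5 within the grid.
    """
    x = curve.grid.points()
    f = curve.probs[pair[0]] - 0.5
    crossings = []
    slopes = []
    exact = np.nonzero(f == 0.0)[0]
    h = curve.grid.spacing
    for i in exact:
        j = min(int(i), len(f) - 2)
        crossings.append(float(x[i]))
        slopes.append(float((f[j + 1] - f[j]) / h))
    change = np.nonzero(f[:-1] * f[1:] < 0.0)[0]
    for i in change:
        xi = x[i] - f[i] * (x[i + 1] - x[i]) / (f[i + 1] - f[i])
        crossings.append(float(xi))
        slopes.append(float((f[i + 1] - f[i]) / h))
    if not crossings:
        raise BoundaryNotFoundError(
            f"P({pair[0].value}) never crosses 0.5 on [{curve.grid.lo}, {curve.grid.hi}]"
        )
    if len(crossings) == 1:
        k = 0
    else:
        if reference is None:
            raise ValueError(
                f"{len(crossings)} crossings at {sorted(crossings)}; "
                "pass `reference` to disambiguate"
            )
        k = int(np.argmin([abs(c - reference) for c in crossings]))
    return Boundary(pair=tuple(pair), location=crossings[k], slope=slopes[k])
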
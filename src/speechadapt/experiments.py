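"""Simulation protocol: pre/post scenarios, metrics, and correlation sweeps.

A scenario compares the stable states before and after adaptation.  Its two
behavioral metrics are

* **compensation fraction** — displacement of the fusion-based production
  posterior for the perturbed vowel, in units of the perturbation and counted
  positive when opposite to it (1 = complete compensation);
* **perceptual boundary shift** — displacement of the 0.5 crossing of a
  categorization curve, per side of the perturbed vowel, in units of the
  perturbation and counted positive in its direction.

The correlation experiment sweeps sources of simulated inter-subject
variability — internal-model update magnitude, auditory-characterization
narrowing, and relative sensory precision — and correlates compensation with
the perceptual shift on the /i-ɛ/ side for each perception/adaptation
hypothesis combination.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .adaptation import AdaptationSpec, Perturbation, build_adapted_state
from .errors import ConfigurationError
from .inference import (
    ProductionPosterior,
    categorization_curve,
    find_boundary,
    production_posterior,
)
from .model import (
    AUDITORY,
    FUSION,
    AxisGrid,
    GaussianCharacterization,
    ModelState,
    Phoneme,
    PHONEMES,
    build_normal_state,
    default_grid,
)

__all__ = [
    "QUESTIONS",
    "SIDES",
    "DEFAULT_COMBOS",
    "BoundaryShift",
    "ScenarioResult",
    "CorrelationTable",
    "compensation_fraction",
    "run_scenario",
    "correlation_experiment",
    "pearson_r",
]

#: Perception questions by identifier: auditory pathway only, or fusion.
QUESTIONS = {"QPerA": AUDITORY, "QPerF": FUSION}

#: Boundary sides around the perturbed vowel, as ordered phoneme pairs.
SIDES: Dict[str, Tuple[Phoneme, Phoneme]] = {
    "i_eh": (Phoneme.I, Phoneme.EH),
    "eh_ah": (Phoneme.EH, Phoneme.AH),
}

#: The three perception/adaptation combinations retained by the protocol.
DEFAULT_COMBOS = ("QPerF+HAdM", "QPerA+HAdMPhi", "QPerF+HAdMPhi")


def compensation_fraction(
    normal: ProductionPosterior,
    adapted: ProductionPosterior,
    pert: Perturbation,
) -> float:
    """(pre mean - post mean) / delta: positive = opposite the perturbation."""
    if pert.delta == 0.0:
        raise ConfigurationError("compensation undefined for a zero perturbation")
    return (normal.mean - adapted.mean) / pert.delta


@dataclass(frozen=True)
class BoundaryShift:
    """One boundary before/after adaptation; shift is in |delta| units."""

    pre: float
    post: float
    shift: float
    pre_slope: float
    post_slope: float


@dataclass(frozen=True)
class ScenarioResult:
    """Metrics of one adaptation scenario."""

    compensation_fraction: float
    production_pre: dict
    production_post: dict
    boundaries: Dict[str, Dict[str, BoundaryShift]]  # question -> side -> shift
    perturbation: Perturbation

    def boundary_shift(self, question: str, side: str) -> float:
        return self.boundaries[question][side].shift

    def to_dict(self) -> dict:
        primary = "QPerF" if "QPerF" in self.boundaries else next(iter(self.boundaries))
        out = {
            "compensation_fraction": self.compensation_fraction,
            "boundary_shift_ie": self.boundaries[primary]["i_eh"].shift,
            "boundary_shift_ea": self.boundaries[primary]["eh_ah"].shift,
            "primary_question": primary,
            "perturbation_delta": self.perturbation.delta,
            "production_pre": self.production_pre,
            "production_post": self.production_post,
            "boundaries": {
                q: {
                    side: {
                        "pre": bs.pre,
                        "post": bs.post,
                        "shift": bs.shift,
                        "pre_slope": bs.pre_slope,
                        "post_slope": bs.post_slope,
                    }
                    for side, bs in sides.items()
                }
                for q, sides in self.boundaries.items()
            },
        }
        return out


def run_scenario(
    adaptation: AdaptationSpec,
    pert: Perturbation,
    perception: Sequence[str] = ("QPerA", "QPerF"),
    grid: Optional[AxisGrid] = None,
    normal: Optional[ModelState] = None,
) -> ScenarioResult:
    """Simulate the pre/post protocol for one adaptation scenario.

    Builds the normal and adapted states, computes fusion production
    posteriors for the perturbed vowel before and after adaptation, and the
    categorization curves for each requested perception question, returning
    the compensation fraction and signed boundary shifts on both sides.
    """
    grid = grid if grid is not None else default_grid()
    normal = normal if normal is not None else build_normal_state()
    for q in perception:
        if q not in QUESTIONS:
            raise ConfigurationError(
                f"unknown perception question {q!r}; expected one of {sorted(QUESTIONS)}"
            )
    adapted = build_adapted_state(normal, adaptation, pert)

    pre_prod = production_posterior(normal, pert.target, FUSION, grid)
    post_prod = production_posterior(adapted, pert.target, FUSION, grid)
    comp = compensation_fraction(pre_prod, post_prod, pert)

    boundaries: Dict[str, Dict[str, BoundaryShift]] = {}
    for q in perception:
        pathways = QUESTIONS[q]
        pre_curve = categorization_curve(normal, grid, pathways)
        post_curve = categorization_curve(adapted, grid, pathways)
        per_side: Dict[str, BoundaryShift] = {}
        for side, pair in SIDES.items():
            ref = 0.5 * (
                normal.aud_chars[pair[0]].mean + normal.aud_chars[pair[1]].mean
            )
            pre_b = find_boundary(pre_curve, pair, reference=ref)
            post_b = find_boundary(post_curve, pair, reference=pre_b.location)
            per_side[side] = BoundaryShift(
                pre=pre_b.location,
                post=post_b.location,
                shift=(post_b.location - pre_b.location) / pert.delta,
                pre_slope=pre_b.slope,
                post_slope=post_b.slope,
            )
        boundaries[q] = per_side

    return ScenarioResult(
        compensation_fraction=comp,
        production_pre=pre_prod.summary(),
        production_post=post_prod.summary(),
        boundaries=boundaries,
        perturbation=pert,
    )


def pearson_r(xs: Iterable[float], ys: Iterable[float]) -> float:
    """Pearson product-moment correlation; NaN flags zero variance.

    Raises
    ------
    ConfigurationError
        On unequal lengths or fewer than 3 points.
    """
    x = np.asarray(list(xs), dtype=float)
    y = np.asarray(list(ys), dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ConfigurationError("pearson_r needs equal-length sequences of >= 3 values")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def _spearman_r(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def _with_som_sd(state: ModelState, sd: float) -> ModelState:
    """Normal state whose somatosensory characterizations all have sd ``sd``."""
    chars = {
        p: GaussianCharacterization(state.som_chars[p].mean, sd) for p in PHONEMES
    }
    return state.replace(som_chars=chars)


@dataclass(frozen=True)
class CorrelationTable:
    """Sweep rows plus one correlation per (combo, somatosensory sd)."""

    rows: pd.DataFrame
    summary: pd.DataFrame
    method: str = "pearson"

    def r(self, combo: str, sigma_s: float) -> float:
        sel = self.summary[
            (self.summary["combo"] == combo)
            & np.isclose(self.summary["sigma_s"], sigma_s)
        ]
        return float(sel["r"].iloc[0])


def default_sigma_grid(sigma0: float = 0.125, n: int = 6) -> Tuple[float, ...]:
    """Evenly spaced target sds from the normal value down to half of it."""
    return tuple(np.linspace(sigma0, sigma0 / 2.0, n))


def correlation_experiment(
    combos: Sequence[str] = DEFAULT_COMBOS,
    update_magnitudes: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    sigma_grid: Optional[Sequence[float]] = None,
    sigma_s_values: Sequence[float] = (0.125,),
    pert: Optional[Perturbation] = None,
    grid: Optional[AxisGrid] = None,
    method: str = "pearson",
    spacing: float = 1.0,
    sigma_frac: float = 0.125,
) -> CorrelationTable:
    """Sweep simulated-subject parameters and correlate the two metrics.

    For each somatosensory sd (relative sensory precision) and each
    perception/adaptation combination, scenarios are run over the
    internal-model update magnitudes — crossed with the auditory-
    characterization sd grid for the combos that include that update — and
    the correlation between compensation and the /i-ɛ/-side perceptual shift
    is computed across the swept points.
    """
    if method not in ("pearson", "spearman"):
        raise ConfigurationError(f"correlation method must be 'pearson' or 'spearman', got {method!r}")
    pert = pert if pert is not None else Perturbation()
    grid = grid if grid is not None else default_grid()
    base = build_normal_state(spacing=spacing, sigma_frac=sigma_frac)
    if sigma_grid is None:
        sigma_grid = default_sigma_grid(sigma_frac * spacing)
    for combo in combos:
        if combo not in DEFAULT_COMBOS:
            raise ConfigurationError(
                f"unknown combo {combo!r}; expected subset of {DEFAULT_COMBOS}"
            )

    records = []
    for sigma_s in sigma_s_values:
        normal = _with_som_sd(base, sigma_s)
        for combo in combos:
            question = combo.split("+", 1)[0]
            with_char = combo.endswith("HAdMPhi")
            if with_char:
                points = list(itertools.product(update_magnitudes, sigma_grid))
            else:
                points = [(m, None) for m in update_magnitudes]
            for mag, sig_eh in points:
                spec = AdaptationSpec(
                    internal_model="local",
                    update_magnitude=mag,
                    aud_char_sigma=sig_eh,
                )
                res = run_scenario(
                    spec, pert, perception=(question,), grid=grid, normal=normal
                )
                records.append(
                    {
                        "combo": combo,
                        "sigma_s": sigma_s,
                        "update_magnitude": mag,
                        "sigma_eh": np.nan if sig_eh is None else sig_eh,
                        "compensation": res.compensation_fraction,
                        "perceptual_shift_ie": res.boundary_shift(question, "i_eh"),
                        "perceptual_shift_ea": res.boundary_shift(question, "eh_ah"),
                    }
                )
    rows = pd.DataFrame.from_records(records)

    corr = pearson_r if method == "pearson" else (
        lambda xs, ys: _spearman_r(np.asarray(list(xs)), np.asarray(list(ys)))
    )
    summaries = []
    for (combo, sigma_s), grp in rows.groupby(["combo", "sigma_s"], sort=False):
        r = corr(grp["compensation"], grp["perceptual_shift_ie"])
        summaries.append(
            {
                "combo": combo,
                "sigma_s": sigma_s,
                "r": r,
                "r_defined": bool(np.isfinite(r)),
                "n_points": len(grp),
            }
        )
    summary = pd.DataFrame.from_records(summaries)
    return CorrelationTable(rows=rows, summary=summary, method=method)
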
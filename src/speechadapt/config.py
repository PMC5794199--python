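"""Scenario configuration, serialization, and canonical scenario suite.

Every experiment is reproducible from a single YAML/JSON document; the model
is fully deterministic, so identical configurations yield byte-identical
outputs.  A minimal empty document expands to the reference protocol: a
perturbation of +0.4 D toward /a/, characterization sd 1/8 D, a local
internal-model update at full magnitude, and fusion-based production.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .adaptation import AdaptationSpec, LocalWindow, Perturbation
from .errors import ConfigurationError
from .experiments import (
    DEFAULT_COMBOS,
    CorrelationTable,
    ScenarioResult,
    default_sigma_grid,
)
from .model import AxisGrid, Phoneme

__all__ = [
    "SweepConfig",
    "ScenarioConfig",
    "load_config",
    "write_results",
    "make_fixture_suite",
]


def _require_keys(d: Mapping, allowed: Sequence[str], context: str) -> None:
    unknown = set(d) - set(allowed)
    if unknown:
        raise ConfigurationError(
            f"unknown field(s) {sorted(unknown)} in {context}; allowed: {sorted(allowed)}"
        )


@dataclass(frozen=True)
class SweepConfig:
    """Parameter grids of the correlation experiment."""

    combos: Tuple[str, ...] = DEFAULT_COMBOS
    update_magnitudes: Tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    sigma_eh_values: Optional[Tuple[float, ...]] = None  # None -> sd0 .. sd0/2
    sigma_s_values: Tuple[float, ...] = (0.125,)
    correlation: str = "pearson"

    def __post_init__(self) -> None:
        if self.correlation not in ("pearson", "spearman"):
            raise ConfigurationError(
                f"correlation must be 'pearson' or 'spearman', got {self.correlation!r}"
            )
        for m in self.update_magnitudes:
            if not 0.0 <= m <= 1.0:
                raise ConfigurationError(
                    f"update_magnitudes entries must be in [0, 1], got {m}"
                )

    def to_dict(self) -> dict:
        return {
            "combos": list(self.combos),
            "update_magnitudes": list(self.update_magnitudes),
            "sigma_eh_values": None
            if self.sigma_eh_values is None
            else list(self.sigma_eh_values),
            "sigma_s_values": list(self.sigma_s_values),
            "correlation": self.correlation,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SweepConfig":
        _require_keys(
            d,
            ["combos", "update_magnitudes", "sigma_eh_values", "sigma_s_values", "correlation"],
            "sweep",
        )
        kwargs = {}
        if "combos" in d:
            kwargs["combos"] = tuple(d["combos"])
        if "update_magnitudes" in d:
            kwargs["update_magnitudes"] = tuple(float(m) for m in d["update_magnitudes"])
        if d.get("sigma_eh_values") is not None:
            kwargs["sigma_eh_values"] = tuple(float(s) for s in d["sigma_eh_values"])
        if "sigma_s_values" in d:
            kwargs["sigma_s_values"] = tuple(float(s) for s in d["sigma_s_values"])
        if "correlation" in d:
            kwargs["correlation"] = str(d["correlation"])
        return cls(**kwargs)


def _adaptation_to_dict(spec: AdaptationSpec) -> dict:
    return {
        "internal_model": spec.internal_model,
        "update_magnitude": spec.update_magnitude,
        "aud_char_sigma": spec.aud_char_sigma,
        "som_char_shift": spec.som_char_shift,
        "local_window": None
        if spec.local_window is None
        else {
            "core_lo": spec.local_window.core_lo,
            "core_hi": spec.local_window.core_hi,
            "ramp": spec.local_window.ramp,
        },
    }


def _adaptation_from_dict(d: Mapping) -> AdaptationSpec:
    _require_keys(
        d,
        ["internal_model", "update_magnitude", "aud_char_sigma", "som_char_shift", "local_window"],
        "adaptation",
    )
    window = None
    if d.get("local_window") is not None:
        w = d["local_window"]
        _require_keys(w, ["core_lo", "core_hi", "ramp"], "adaptation.local_window")
        window = LocalWindow(float(w["core_lo"]), float(w["core_hi"]), float(w["ramp"]))
    return AdaptationSpec(
        internal_model=str(d.get("internal_model", "local")),
        update_magnitude=float(d.get("update_magnitude", 1.0)),
        aud_char_sigma=None if d.get("aud_char_sigma") is None else float(d["aud_char_sigma"]),
        som_char_shift=None if d.get("som_char_shift") is None else float(d["som_char_shift"]),
        local_window=window,
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to reproduce one scenario or sweep bit-exactly."""

    spacing: float = 1.0
    sigma_frac: float = 0.125
    grid: AxisGrid = field(default_factory=AxisGrid)
    perturbation: Perturbation = field(default_factory=Perturbation)
    adaptation: AdaptationSpec = field(
        default_factory=lambda: AdaptationSpec(internal_model="local", update_magnitude=1.0)
    )
    perception: Tuple[str, ...] = ("QPerA", "QPerF")
    sweep: SweepConfig = field(default_factory=SweepConfig)

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise ConfigurationError(f"spacing must be > 0, got {self.spacing}")
        if not self.sigma_frac > 0:
            raise ConfigurationError(f"sigma_frac must be > 0, got {self.sigma_frac}")

    def sigma_eh_grid(self) -> Tuple[float, ...]:
        if self.sweep.sigma_eh_values is not None:
            return self.sweep.sigma_eh_values
        return default_sigma_grid(self.sigma_frac * self.spacing)

    def to_dict(self) -> dict:
        return {
            "spacing": self.spacing,
            "sigma_frac": self.sigma_frac,
            "grid": self.grid.to_dict(),
            "perturbation": {
                "delta": self.perturbation.delta,
                "target": self.perturbation.target.value,
            },
            "adaptation": _adaptation_to_dict(self.adaptation),
            "perception": list(self.perception),
            "sweep": self.sweep.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        _require_keys(
            d,
            ["spacing", "sigma_frac", "grid", "perturbation", "adaptation", "perception", "sweep"],
            "scenario config",
        )
        kwargs = {}
        if "spacing" in d:
            kwargs["spacing"] = float(d["spacing"])
        if "sigma_frac" in d:
            kwargs["sigma_frac"] = float(d["sigma_frac"])
        if "grid" in d:
            _require_keys(d["grid"], ["lo", "hi", "n"], "grid")
            kwargs["grid"] = AxisGrid.from_dict(d["grid"])
        if "perturbation" in d:
            p = d["perturbation"]
            _require_keys(p, ["delta", "target"], "perturbation")
            kwargs["perturbation"] = Perturbation(
                delta=float(p.get("delta", 0.4)),
                target=Phoneme(p.get("target", "eh")),
            )
        if "adaptation" in d:
            kwargs["adaptation"] = _adaptation_from_dict(d["adaptation"])
        if "perception" in d:
            kwargs["perception"] = tuple(d["perception"])
        if "sweep" in d:
            kwargs["sweep"] = SweepConfig.from_dict(d["sweep"])
        return cls(**kwargs)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_config(path) -> ScenarioConfig:
    """Parse and validate a YAML or JSON scenario document.

    An empty document yields the full default configuration (the reference
    adaptation protocol).  Schema violations raise ``ConfigurationError``
    naming the offending field.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"could not parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"top level of {path} must be a mapping")
    return ScenarioConfig.from_dict(raw)


def write_results(result, path) -> None:
    """Write a scenario result (JSON) or correlation table (CSV) to ``path``.

    Correlation tables produce two files: the sweep rows at ``path`` and the
    per-combo correlation summary at ``<path stem>.summary.csv``.  Numbers
    are written at full double precision.
    """
    path = Path(path)
    try:
        if isinstance(result, ScenarioResult):
            path.write_text(json.dumps(result.to_dict(), indent=2))
        elif isinstance(result, CorrelationTable):
            result.rows.to_csv(path, index=False, float_format="%.17g")
            summary_path = path.with_suffix(".summary.csv")
            result.summary.to_csv(summary_path, index=False, float_format="%.17g")
        elif isinstance(result, pd.DataFrame):
            result.to_csv(path, index=False, float_format="%.17g")
        else:
            raise ConfigurationError(
                f"cannot serialize result of type {type(result).__name__}"
            )
    except OSError as exc:
        raise ConfigurationError(f"could not write results to {path}: {exc}") from exc


def make_fixture_suite() -> Dict[str, ScenarioConfig]:
    """Canonical scenario configurations covering every adaptation hypothesis.

    Includes the no-update control, general and local internal-model updates,
    each single characterization update, the combined update, and the two
    correlation sweeps (equal sensory precision, and the three-valued
    somatosensory-precision grid).
    """
    none = AdaptationSpec(internal_model="none", update_magnitude=0.0)
    suite = {
        "normal": ScenarioConfig(adaptation=none),
        "hadm_general": ScenarioConfig(
            adaptation=AdaptationSpec(internal_model="general", update_magnitude=1.0)
        ),
        "hadm_local": ScenarioConfig(
            adaptation=AdaptationSpec(internal_model="local", update_magnitude=1.0)
        ),
        "hadphi": ScenarioConfig(
            adaptation=AdaptationSpec(internal_model="none", aud_char_sigma=0.0625)
        ),
        "hads": ScenarioConfig(
            # magnitude matches the compensation displacement of the local
            # full update under equal sensory precision (0.5 * 0.4 D)
            adaptation=AdaptationSpec(internal_model="none", som_char_shift=-0.2)
        ),
        "hadmphi": ScenarioConfig(
            adaptation=AdaptationSpec(
                internal_model="local", update_magnitude=1.0, aud_char_sigma=0.0625
            )
        ),
        "sweep_equal_precision": ScenarioConfig(
            sweep=SweepConfig(sigma_s_values=(0.125,))
        ),
        "sweep_sensory_precision": ScenarioConfig(
            sweep=SweepConfig(sigma_s_values=(0.125, 1.0 / 6.0, 0.25))
        ),
    }
    return suite
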
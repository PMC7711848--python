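"""Macro-kinetic model parameters for E. coli overflow-metabolism growth.

The model carries 18 parameters: 13 phenotype-specific (estimable) rate,
affinity and yield constants, plus 5 that are fixed by the operating setup
(maintenance ``qm``, overflow saturation ``Kap``, oxygen transfer ``kLa``,
DOT saturation ``DOTstar`` and the enzymatic glucose-release rate ``kP``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping

import numpy as np

#: Estimable (clone-specific) parameters, in the conventional reporting order.
ESTIMABLE_PARAMETERS: tuple[str, ...] = (
    "qAmax", "Kaq", "Ksq", "Yam", "Yaresp", "Yem", "qSmax",
    "Ks", "Ko", "Yosresp", "pAmax", "Yaof", "Yofm",
)

#: Parameters held fixed during calibration (setup-specific, not phenotype).
FIXED_PARAMETERS: tuple[str, ...] = ("qm", "Kap", "kLa", "DOTstar", "kP")

ALL_PARAMETERS: tuple[str, ...] = ESTIMABLE_PARAMETERS + FIXED_PARAMETERS

#: Biomass/acetate yields are bounded above by stoichiometric plausibility.
YIELD_CAP = 1.2
_CAPPED_YIELDS = ("Yem", "Yofm", "Yam", "Yaof")


@dataclass
class ModelParameters:
    """The 18-parameter vector of the macro-kinetic growth model.

    Units: specific rates ``q*`` and ``qm`` in g g^-1 h^-1; affinities
    ``Ks``, ``Kaq``, ``Ksq`` in g L^-1; ``Ko`` in % DOT; ``Kap`` in
    g g^-1 h^-1; yields in g g^-1; ``kLa`` and ``kP`` in h^-1;
    ``DOTstar`` in % air saturation.
    """

    # estimable
    qAmax: float = 1.0252   # max specific acetate uptake rate
    Kaq: float = 0.2133     # acetate-uptake affinity
    Ksq: float = 1.0667     # glucose repression of acetate uptake
    Yam: float = 0.1955     # biomass yield on acetate
    Yaresp: float = 0.1672  # oxygen demand per acetate respired
    Yem: float = 0.56       # biomass yield on oxidative glucose
    qSmax: float = 1.3431   # max specific glucose uptake rate
    Ks: float = 0.05        # glucose affinity
    Ko: float = 1.0         # oxygen saturation constant (% DOT)
    Yosresp: float = 1.0    # oxygen demand per glucose respired
    pAmax: float = 1.3091   # max overflow-pathway glucose flux
    Yaof: float = 0.4607    # acetate yield on overflow glucose
    Yofm: float = 0.2795    # biomass yield on overflow glucose
    # fixed
    qm: float = 0.04        # maintenance coefficient
    Kap: float = 2.0        # overflow-flux saturation constant
    kLa: float = 1000.0     # volumetric oxygen transfer coefficient
    DOTstar: float = 100.0  # DOT at air saturation
    kP: float = 0.0         # enzymatic glucose-release rate (main culture: 0)

    #: dissolved-oxygen solubility at cultivation temperature, g L^-1;
    #: converts between % DOT and g L^-1 oxygen in the DOT balance.
    cO2sat: float = 0.0067

    bounds: dict[str, tuple[float, float]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.validate()
        if not self.bounds:
            self.bounds = default_bounds(self)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        for name in ALL_PARAMETERS:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"parameter {name} must be finite and >= 0, got {v!r}")
        for name in _CAPPED_YIELDS:
            v = getattr(self, name)
            if v > YIELD_CAP:
                raise ValueError(f"yield {name}={v} exceeds cap {YIELD_CAP}")
        if self.cO2sat <= 0:
            raise ValueError("cO2sat must be positive")

    # -- array round trip ---------------------------------------------------

    def to_array(self, names: Iterable[str] = ESTIMABLE_PARAMETERS) -> np.ndarray:
        return np.array([getattr(self, n) for n in names], dtype=float)

    def with_values(self, names: Iterable[str], values: Iterable[float]) -> "ModelParameters":
        """A copy with the named parameters replaced."""
        updates = dict(zip(list(names), [float(v) for v in values], strict=True))
        new = replace(self, **updates)
        new.bounds = dict(self.bounds)
        return new

    def copy(self) -> "ModelParameters":
        new = replace(self)
        new.bounds = dict(self.bounds)
        return new

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        out: dict = {}
        for name in ALL_PARAMETERS:
            entry: dict = {"value": getattr(self, name)}
            if name in self.bounds:
                lo, hi = self.bounds[name]
                entry["lower"], entry["upper"] = lo, hi
            entry["fixed"] = name in FIXED_PARAMETERS
            out[name] = entry
        out["cO2sat"] = {"value": self.cO2sat, "fixed": True}
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "ModelParameters":
        values: dict = {}
        bounds: dict[str, tuple[float, float]] = {}
        for name, entry in data.items():
            if name not in ALL_PARAMETERS and name != "cO2sat":
                raise KeyError(f"unknown parameter {name!r}")
            if isinstance(entry, Mapping):
                values[name] = float(entry["value"])
                if "lower" in entry or "upper" in entry:
                    bounds[name] = (
                        float(entry.get("lower", 0.0)),
                        float(entry.get("upper", math.inf)),
                    )
            else:
                values[name] = float(entry)
        params = cls(**values)
        if bounds:
            params.bounds.update(bounds)
        return params

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


#: Expert physiological windows for aerobically grown E. coli; they contain
#: the initial guesses and the spread of fitted values across clone screens.
#: Without such bounds the sloppy directions of the model admit wildly
#: non-physiological compensating optima.
EXPERT_BOUNDS: dict[str, tuple[float, float]] = {
    "qSmax": (0.4, 2.5),
    "Ks": (0.005, 0.5),
    "Ko": (0.05, 25.0),
    "qAmax": (0.1, 4.0),
    "Kaq": (0.02, 2.0),
    "Ksq": (0.1, 10.0),
    "pAmax": (0.1, 2.0),
    "Yem": (0.3, 0.75),
    "Yofm": (0.05, 0.6),
    "Yam": (0.1, 0.8),
    "Yaof": (0.05, 0.9),
    "Yosresp": (0.5, 2.5),
    "Yaresp": (0.05, 1.5),
}


def default_bounds(params: ModelParameters) -> dict[str, tuple[float, float]]:
    """Expert-knowledge box bounds, widened if needed so the current value
    always lies inside."""
    bounds: dict[str, tuple[float, float]] = {}
    for name in ESTIMABLE_PARAMETERS:
        v = getattr(params, name)
        lo, hi = EXPERT_BOUNDS[name]
        lo, hi = min(lo, v / 2.0) if v > 0 else 0.0, max(hi, v * 1.5)
        if name in _CAPPED_YIELDS:
            hi = min(hi, YIELD_CAP)
        bounds[name] = (lo, hi)
    return bounds


# Fitted parameter sets after a completed screening campaign, usable as
# realistic clone phenotypes for the virtual plant.  Keys are strain labels;
# values follow ESTIMABLE_PARAMETERS order.
STRAIN_PRESETS: dict[str, tuple[float, ...]] = {
    "W3110":  (1.59, 0.59, 1.52, 0.40, 0.15, 0.60, 1.60, 0.03, 19.87, 2.00, 1.60, 0.35, 0.20),
    "BW25113": (0.52, 0.55, 1.98, 0.41, 0.15, 0.60, 1.58, 0.03, 18.13, 2.00, 0.93, 0.20, 0.20),
    "dompT":  (0.90, 0.98, 1.97, 0.44, 0.15, 0.60, 1.60, 0.03, 14.51, 1.99, 1.13, 0.24, 0.22),
    "daceA":  (0.56, 0.98, 1.91, 0.44, 0.12, 0.58, 1.47, 0.08, 18.64, 1.80, 0.86, 0.21, 0.21),
    "dfliA":  (0.72, 0.60, 1.77, 0.48, 0.15, 0.60, 1.59, 0.03, 16.29, 1.76, 0.95, 0.21, 0.23),
    "dgatC":  (0.68, 0.68, 1.99, 0.44, 0.15, 0.60, 1.55, 0.03, 16.00, 1.97, 0.98, 0.20, 0.21),
    "dgatZ":  (0.86, 0.75, 1.63, 0.44, 0.13, 0.58, 1.39, 0.04, 14.13, 1.89, 1.08, 0.23, 0.22),
    "dglcB":  (0.71, 0.70, 1.68, 0.42, 0.13, 0.59, 1.40, 0.03, 9.57, 1.19, 0.87, 0.23, 0.22),
}


def initial_guess() -> ModelParameters:
    """The expert initial-guess parameter set used before any calibration."""
    return ModelParameters()


def strain_preset(name: str) -> ModelParameters:
    """A fitted whole-campaign parameter set for the named strain."""
    try:
        values = STRAIN_PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown strain {name!r}; available: {sorted(STRAIN_PRESETS)}") from None
    base = ModelParameters()
    out = base.with_values(ESTIMABLE_PARAMETERS, values)
    # re-center bounds on the preset, not on the initial guess
    out.bounds = default_bounds(out)
    return out
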
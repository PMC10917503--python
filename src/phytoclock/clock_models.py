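"""Compact plant circadian clock models.

The base oscillator lumps eight clock genes into four mRNA/protein pairs --
CL (CCA1/LHY), P97 (PRR9/PRR7), P51 (TOC1/PRR5), EL (ELF4/LUX) -- plus a
dark-accumulating, light-degraded factor P that mediates acute light
induction at dawn (9 state variables).  Three 11-state variants split the
merged P97 component into separate P9 and P7 gene copies:

* ``MODEL1`` -- the split copies keep exactly the merged component's wiring.
* ``MODEL2`` -- additionally, CL represses P9 transcription through a squared
  Hill term with half-max constant ``K11 = (K4 + K5) / 2``.
* ``MODEL3`` -- CL represses both P9 and P7 (same ``K11`` term) and CL gains a
  negative autoregulation term with configurable half-max ``K_auto``.

All regulatory terms are squared Hill functions.  Light enters through a
square (optionally twilight-smoothed) forcing ``L(t)`` in [0, 1] with
``D = 1 - L``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "Release",
    "SplitCoupling",
    "LightProtocol",
    "ModelVariant",
    "ParameterSet",
    "VARIANTS",
    "get_variant",
    "evaluate_light",
    "derive_K11",
    "rhs",
    "load_base_parameters",
    "parameters_for_variant",
    "split_parameter_names",
    "HILL_EXPONENT",
]

HILL_EXPONENT = 2

_PARAM_DIR = Path(__file__).parent / "params"

# Constants shared by every variant.
_SHARED_NAMES = (
    "v1", "v1L", "k1L", "k1D", "p1", "p1L", "d1",
    "v3", "k3", "p3", "d3D", "d3L",
    "v4", "k4", "p4", "d4D", "d4L",
    "K1", "K2", "K4", "K5", "K6", "K7", "K8", "K10",
    "pP",
)

# Per-P-gene constants: merged in BASE, duplicated per copy in split variants.
_P_GENE_NAMES = ("v2A", "v2L", "k2", "p2", "d2D", "d2L")


class Release(enum.Enum):
    """Free-run light condition after entrainment."""

    CONSTANT_LIGHT = "LL"
    CONSTANT_DARK = "DD"


class SplitCoupling(enum.Enum):
    """How downstream targets read the split P9/P7 proteins.

    SUM_HALVED: every Hill term that read [P97]p now reads ([P9]p + [P7]p)
    with the original half-max constant, and each copy's production rates are
    half the merged gene's, so the wild-type split model reproduces the base
    model exactly.

    INDEPENDENT_FULL: each copy contributes its own Hill term (same half-max)
    and keeps the merged gene's full production rates.
    """

    SUM_HALVED = "sum_halved"
    INDEPENDENT_FULL = "independent_full"


class ClockModelError(Exception):
    """Base error for model construction/evaluation problems."""


class StateShapeError(ClockModelError):
    """State vector length does not match the model variant."""


class IncompleteParametersError(ClockModelError):
    """A required rate or Hill constant is missing."""


@dataclass(frozen=True)
class LightProtocol:
    """Entrainment followed by release into constant conditions.

    Defaults follow the simulated protocol: 8 days of 12 h light / 12 h dark
    then release into constant light.
    """

    entrain_days: int = 8
    photoperiod_light_h: float = 12.0
    cycle_h: float = 24.0
    release: Release = Release.CONSTANT_LIGHT
    free_run_days: int = 6
    twilight_h: float = 0.05

    def __post_init__(self) -> None:
        if self.entrain_days < 0:
            raise ValueError("entrain_days must be non-negative")
        if self.free_run_days <= 0:
            raise ValueError("free_run_days must be positive")
        if not 0 <= self.photoperiod_light_h <= self.cycle_h:
            raise ValueError("photoperiod_light_h must lie in [0, cycle_h]")
        if self.twilight_h < 0:
            raise ValueError("twilight_h must be non-negative")
        if self.twilight_h > 0 and self.twilight_h > 0.25 * self.photoperiod_light_h:
            raise ValueError("twilight_h must be small compared to the photoperiod")

    @property
    def release_time_h(self) -> float:
        return self.entrain_days * self.cycle_h

    @property
    def total_h(self) -> float:
        return self.release_time_h + self.free_run_days * 24.0

    def light_transitions(self) -> list[float]:
        """Times (h) of lights-on/lights-off edges during entrainment."""
        edges: list[float] = []
        for day in range(self.entrain_days):
            t0 = day * self.cycle_h
            edges.append(t0)
            edges.append(t0 + self.photoperiod_light_h)
        edges.append(self.release_time_h)
        return edges


def evaluate_light(protocol: LightProtocol, t):
    """Light level L(t) in [0, 1].

    Scalar or array ``t`` (hours, >= 0).  Square wave during entrainment with
    optional sigmoidal twilight of half-width ``twilight_h``; constant at the
    release value afterwards.  Darkness is ``D = 1 - L`` everywhere.
    """
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("time must be non-negative")
    release_level = 1.0 if protocol.release is Release.CONSTANT_LIGHT else 0.0
    phase = np.mod(arr, protocol.cycle_h)
    if protocol.twilight_h == 0:
        entrained = (phase < protocol.photoperiod_light_h).astype(float)
    else:
        w = protocol.twilight_h
        rise = 1.0 / (1.0 + np.exp(-phase / w))
        fall = 1.0 / (1.0 + np.exp((phase - protocol.photoperiod_light_h) / w))
        entrained = rise * fall
    out = np.where(arr >= protocol.release_time_h, release_level, entrained)
    if np.isscalar(t) or arr.ndim == 0:
        return float(out)
    return out


def derive_K11(K4: float, K5: float) -> float:
    """Half-max constant for CL repression of the split P genes: (K4 + K5)/2."""
    if K4 <= 0 or K5 <= 0:
        raise ValueError("Hill constants must be positive")
    return (K4 + K5) / 2.0


@dataclass(frozen=True)
class ModelVariant:
    name: str
    component_names: tuple[str, ...]
    split: bool

    @property
    def n_states(self) -> int:
        return len(self.component_names)

    def index(self, component: str) -> int:
        try:
            return self.component_names.index(component)
        except ValueError:
            raise KeyError(f"unknown component {component!r} for {self.name}") from None


_BASE_COMPONENTS = (
    "CL_m", "CL_p", "P97_m", "P97_p", "P51_m", "P51_p", "EL_m", "EL_p", "P",
)
_SPLIT_COMPONENTS = (
    "CL_m", "CL_p", "P9_m", "P9_p", "P7_m", "P7_p",
    "P51_m", "P51_p", "EL_m", "EL_p", "P",
)

VARIANTS: dict[str, ModelVariant] = {
    "BASE": ModelVariant("BASE", _BASE_COMPONENTS, split=False),
    "MODEL1": ModelVariant("MODEL1", _SPLIT_COMPONENTS, split=True),
    "MODEL2": ModelVariant("MODEL2", _SPLIT_COMPONENTS, split=True),
    "MODEL3": ModelVariant("MODEL3", _SPLIT_COMPONENTS, split=True),
}


def get_variant(name: str) -> ModelVariant:
    try:
        return VARIANTS[name.upper()]
    except KeyError:
        raise KeyError(
            f"unknown model variant {name!r}; expected one of {sorted(VARIANTS)}"
        ) from None


def split_parameter_names(variant: ModelVariant) -> tuple[str, ...]:
    """All constant names required by a variant."""
    names = list(_SHARED_NAMES)
    if variant.split:
        for stem in _P_GENE_NAMES:
            names.append(f"{stem}_p9")
            names.append(f"{stem}_p7")
        if variant.name in ("MODEL2", "MODEL3"):
            names.append("K11")
        if variant.name == "MODEL3":
            names.append("K_auto")
    else:
        names.extend(_P_GENE_NAMES)
    return tuple(names)


class ParameterSet(Mapping):
    """Immutable named collection of rate constants and Hill half-maxes.

    Values are validated on construction: every constant must be finite and
    non-negative, and every half-max constant (name starting with ``K``)
    strictly positive.
    """

    def __init__(self, values: Mapping[str, float], variant: str | None = None):
        clean: dict[str, float] = {}
        for name, value in values.items():
            v = float(value)
            if not math.isfinite(v):
                raise ValueError(f"parameter {name} is not finite: {value}")
            if v < 0:
                raise ValueError(f"parameter {name} must be >= 0, got {value}")
            if name.startswith("K") and v <= 0:
                raise ValueError(f"Hill constant {name} must be > 0, got {value}")
            clean[name] = v
        self._values = clean
        self.variant = variant

    def __getitem__(self, key: str) -> float:
        return self._values[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return self._values == other._values and self.variant == other.variant

    def __repr__(self) -> str:
        return f"ParameterSet(variant={self.variant!r}, n={len(self)})"

    def replace(self, **updates: float) -> "ParameterSet":
        unknown = set(updates) - set(self._values)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        merged = dict(self._values)
        merged.update({k: float(v) for k, v in updates.items()})
        return ParameterSet(merged, variant=self.variant)

    def require(self, names) -> None:
        missing = [n for n in names if n not in self._values]
        if missing:
            raise IncompleteParametersError(
                f"missing parameters for {self.variant or 'model'}: {missing}"
            )

    def to_dict(self) -> dict[str, float]:
        return dict(self._values)

    @classmethod
    def from_yaml(cls, path: str | Path, variant: str | None = None) -> "ParameterSet":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"parameter file {path} must be a flat mapping")
        meta_variant = None
        if "variant" in data:
            meta_variant = str(data.pop("variant"))
        return cls(data, variant=variant or meta_variant)

    def to_yaml(self, path: str | Path) -> None:
        payload: dict[str, object] = {}
        if self.variant:
            payload["variant"] = self.variant
        payload.update({k: float(v) for k, v in sorted(self._values.items())})
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def load_base_parameters() -> ParameterSet:
    """The bundled base-model parameter table."""
    return ParameterSet.from_yaml(_PARAM_DIR / "base.yaml", variant="BASE")


def parameters_for_variant(
    variant: ModelVariant | str,
    base: ParameterSet | None = None,
    coupling: SplitCoupling = SplitCoupling.SUM_HALVED,
    K11: float | None = None,
    K_auto: float = 1.0,
) -> ParameterSet:
    """Build a variant's full parameter set from the base table.

    Split variants duplicate the merged P-gene constants into ``_p9``/``_p7``
    copies.  Under ``SUM_HALVED`` the two copies' transcription rates are each
    half the merged gene's; under ``INDEPENDENT_FULL`` they keep full rates.
    ``K11`` defaults to ``(K4 + K5) / 2``.
    """
    if isinstance(variant, str):
        variant = get_variant(variant)
    if base is None:
        base = load_base_parameters()
    base.require(_SHARED_NAMES)
    base.require(_P_GENE_NAMES)
    if not variant.split:
        return ParameterSet(base.to_dict(), variant=variant.name)

    values = {k: base[k] for k in _SHARED_NAMES}
    halve = coupling is SplitCoupling.SUM_HALVED
    for stem in _P_GENE_NAMES:
        v = base[stem]
        if halve and stem in ("v2A", "v2L"):
            v = v / 2.0
        values[f"{stem}_p9"] = v
        values[f"{stem}_p7"] = v
    if variant.name in ("MODEL2", "MODEL3"):
        values["K11"] = derive_K11(base["K4"], base["K5"]) if K11 is None else float(K11)
    if variant.name == "MODEL3":
        values["K_auto"] = float(K_auto)
    return ParameterSet(values, variant=variant.name)


def _hill2(x: float, K: float) -> float:
    return (x / K) ** HILL_EXPONENT


def rhs(
    variant: ModelVariant | str,
    state,
    t: float,
    params: ParameterSet,
    protocol: LightProtocol,
    coupling: SplitCoupling = SplitCoupling.SUM_HALVED,
):
    """Time derivative of the clock state at time ``t`` (hours).

    ``state`` must have length ``variant.n_states``; ordering follows
    ``variant.component_names``.
    """
    if isinstance(variant, str):
        variant = get_variant(variant)
    y = np.asarray(state, dtype=float)
    if y.shape != (variant.n_states,):
        raise StateShapeError(
            f"{variant.name} expects {variant.n_states} states, got shape {y.shape}"
        )
    params.require(split_parameter_names(variant))
    p = params
    L = evaluate_light(protocol, t)
    D = 1.0 - L

    if not variant.split:
        CLm, CLp, P97m, P97p, P51m, P51p, ELm, ELp, Pacc = y
        dCLm = (p["v1"] + p["v1L"] * L * Pacc) / (
            1.0 + _hill2(P97p, p["K1"]) + _hill2(P51p, p["K2"])
        ) - (p["k1L"] * L + p["k1D"] * D) * CLm
        dCLp = (p["p1"] + p["p1L"] * L) * CLm - p["d1"] * CLp
        dP97m = (p["v2L"] * L * Pacc + p["v2A"]) / (
            1.0 + _hill2(P51p, p["K4"]) + _hill2(ELp, p["K5"])
        ) - p["k2"] * P97m
        dP97p = p["p2"] * P97m - (p["d2D"] * D + p["d2L"] * L) * P97p
        act = _hill2(CLp, p["K6"]) / (1.0 + _hill2(CLp, p["K6"]))
        dP51m = p["v3"] * act / (1.0 + _hill2(ELp, p["K7"])) - p["k3"] * P51m
        dP51p = p["p3"] * P51m - (p["d3D"] * D + p["d3L"] * L) * P51p
        dELm = p["v4"] / (1.0 + _hill2(CLp, p["K8"]) + _hill2(ELp, p["K10"])) - p["k4"] * ELm
        dELp = p["p4"] * ELm - (p["d4D"] * D + p["d4L"] * L) * ELp
        dP = p["pP"] * (1.0 - Pacc) * D - Pacc * L
        return np.array(
            [dCLm, dCLp, dP97m, dP97p, dP51m, dP51p, dELm, dELp, dP]
        )

    CLm, CLp, P9m, P9p, P7m, P7p, P51m, P51p, ELm, ELp, Pacc = y
    # Downstream readout of the split proteins.
    if coupling is SplitCoupling.SUM_HALVED:
        p97_on_cl = _hill2(P9p + P7p, p["K1"])
    else:
        p97_on_cl = _hill2(P9p, p["K1"]) + _hill2(P7p, p["K1"])

    denCL = 1.0 + p97_on_cl + _hill2(P51p, p["K2"])
    if variant.name == "MODEL3":
        denCL += _hill2(CLp, p["K_auto"])
    dCLm = (p["v1"] + p["v1L"] * L * Pacc) / denCL - (p["k1L"] * L + p["k1D"] * D) * CLm
    dCLp = (p["p1"] + p["p1L"] * L) * CLm - p["d1"] * CLp

    den9 = 1.0 + _hill2(P51p, p["K4"]) + _hill2(ELp, p["K5"])
    den7 = 1.0 + _hill2(P51p, p["K4"]) + _hill2(ELp, p["K5"])
    if variant.name in ("MODEL2", "MODEL3"):
        den9 += _hill2(CLp, p["K11"])
    if variant.name == "MODEL3":
        den7 += _hill2(CLp, p["K11"])
    dP9m = (p["v2L_p9"] * L * Pacc + p["v2A_p9"]) / den9 - p["k2_p9"] * P9m
    dP9p = p["p2_p9"] * P9m - (p["d2D_p9"] * D + p["d2L_p9"] * L) * P9p
    dP7m = (p["v2L_p7"] * L * Pacc + p["v2A_p7"]) / den7 - p["k2_p7"] * P7m
    dP7p = p["p2_p7"] * P7m - (p["d2D_p7"] * D + p["d2L_p7"] * L) * P7p

    act = _hill2(CLp, p["K6"]) / (1.0 + _hill2(CLp, p["K6"]))
    dP51m = p["v3"] * act / (1.0 + _hill2(ELp, p["K7"])) - p["k3"] * P51m
    dP51p = p["p3"] * P51m - (p["d3D"] * D + p["d3L"] * L) * P51p
    dELm = p["v4"] / (1.0 + _hill2(CLp, p["K8"]) + _hill2(ELp, p["K10"])) - p["k4"] * ELm
    dELp = p["p4"] * ELm - (p["d4D"] * D + p["d4L"] * L) * ELp
    dP = p["pP"] * (1.0 - Pacc) * D - Pacc * L
    return np.array(
        [dCLm, dCLp, dP9m, dP9p, dP7m, dP7p, dP51m, dP51p, dELm, dELp, dP]
    )
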
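"""Model parameter sets for the CKD and CIA anemia rat PK/PD models.

A :class:`ParameterSet` holds the pharmacodynamic constants of one of the two
disease models:

``ckd``
    adenine-induced chronic-kidney-disease anemia: lifespan/amplification
    erythropoiesis model with direct rHuEPO stimulation of precursor
    production, plus the circadian + induced erythroferrone (ERFE) subsystem.
``cia``
    carboplatin-induced chemotherapy anemia: proliferation/transit
    (Friberg-type) erythropoiesis model with carboplatin kill and RBC
    feedback, plus the same ERFE subsystem.

Primitive parameters carry the published point estimates; derived constants
(the baseline proliferation rate ``K_IN0``, the baseline reticulocyte pool
``RET0``, the shared transit rate ``k_prol = k_circ = k_tr = (N+1)/MTT`` and
all steady-state compartment initials) are always recomputed from the
primitives and are never free.

Residual-error magnitudes (``sigma_*``) are stored on the published
coefficient-of-variation percent scale; :meth:`ParameterSet.sigma_frac`
returns the fractional value used by the likelihood and noise generator.

Drug kinetics constants live in a separate PK config (see
:func:`load_pk_config`); they are fixed inputs, never estimated here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "ParameterSet",
    "ParameterError",
    "load_parameters",
    "load_pk_config",
    "TABLE1",
    "TABLE2",
    "UNITS",
]


class ParameterError(ValueError):
    """Invalid, unknown or out-of-range model parameter."""


#: CKD (adenine) anemia PD point estimates.
TABLE1: Mapping[str, float] = {
    "t_rbc": 1280.0,     # mean RBC lifespan, h
    "t_prec": 20.7,      # mean precursor-stage lifespan, h
    "rbc0": 6.15,        # baseline RBC count, 10^12 cells/L
    "mch": 20.2,         # mean corpuscular hemoglobin, pg/cell
    "gamma": 3.9,        # RBC feedback exponent
    "k_epo": 0.0106,     # first-order rHuEPO stimulation, mL/mIU
    "ampn": 32.0,        # CFU-E per BFU-E amplification (2^5)
    "ampc": 32.0,        # erythroblasts per CFU-E amplification (2^5)
    "k_out": 2.82,       # circadian ERFE elimination, 1/h
    "rm": 7.25,          # ERFE circadian mesor, ng/mL
    "ra": 2.51,          # ERFE circadian amplitude, ng/mL
    "t_peak": 14.9,      # ERFE circadian acrophase, h
    "emax": 47.2,        # max ERFE induction per precursor cell
    "ec50": 1360.0,      # rHuEPO potency for ERFE induction, mIU/mL
    "k_tr": 2.25,        # ERFE transit rate constant, 1/h
    "sigma_rbc": 0.495,  # proportional residual CV, %
    "sigma_hgb": 1.03,
    "sigma_erfe": 1.54,
}

#: CIA (carboplatin) anemia PD point estimates.
TABLE2: Mapping[str, float] = {
    "k_carb": 0.172,     # carboplatin kill effect on precursors
    "mtt": 200.0,        # mean precursor maturation transit time, h
    "n_transit": 3.0,    # number of transit compartments
    "rbc0": 6.46,
    "mch": 21.1,
    "gamma": 0.189,
    "k_epo": 0.0,        # no direct EPO term in the estimates for the CIA model
    "k_out": 1.16,
    "rm": 9.03,
    "ra": 3.69,
    "t_peak": 15.1,
    "emax": 1.16,
    "ec50": 126.0,
    "k_tr": 2.26,
    "sigma_rbc": 0.748,
    "sigma_hgb": 1.51,
    "sigma_erfe": 2.2,
}

UNITS: Mapping[str, str] = {
    "t_rbc": "h",
    "t_prec": "h",
    "rbc0": "10^12 cells/L",
    "mch": "pg/cell",
    "gamma": "-",
    "k_epo": "mL/mIU",
    "ampn": "-",
    "ampc": "-",
    "k_carb": "1/h",
    "mtt": "h",
    "n_transit": "-",
    "k_out": "1/h",
    "rm": "ng/mL",
    "ra": "ng/mL",
    "t_peak": "h",
    "emax": "1/cell",
    "ec50": "mIU/mL",
    "k_tr": "1/h",
    "sigma_rbc": "%CV",
    "sigma_hgb": "%CV",
    "sigma_erfe": "%CV",
}

_SIGMA_NAMES = ("sigma_rbc", "sigma_hgb", "sigma_erfe")
# parameters allowed to be zero (everything else must be strictly positive)
_NONNEG = frozenset({"gamma", "k_epo"})

_MODEL_FIELDS = {
    "ckd": frozenset(TABLE1),
    "cia": frozenset(TABLE2),
}


@dataclass(frozen=True)
class ParameterSet:
    """Immutable, validated PD parameter set for one disease model.

    Parameters are accessed as attributes (``p.ec50``) or items
    (``p["ec50"]``); :meth:`replace` returns a new set with overrides
    applied and every derived constant implicitly recomputed (derived
    quantities are computed on demand from primitives).
    """

    model: str
    values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in _MODEL_FIELDS:
            raise ParameterError(f"unknown model {self.model!r}; expected 'ckd' or 'cia'")
        expected = _MODEL_FIELDS[self.model]
        missing = expected - set(self.values)
        unknown = set(self.values) - expected
        if missing:
            raise ParameterError(f"missing parameters for {self.model}: {sorted(missing)}")
        if unknown:
            raise ParameterError(f"unknown parameters for {self.model}: {sorted(unknown)}")
        object.__setattr__(self, "values", dict(self.values))
        self._validate()

    def _validate(self) -> None:
        for name, value in self.values.items():
            v = float(value)
            if not math.isfinite(v):
                raise ParameterError(f"{name} is not finite")
            if name in _NONNEG:
                if v < 0:
                    raise ParameterError(f"{name} must be >= 0, got {v}")
            elif v <= 0:
                raise ParameterError(f"{name} must be > 0, got {v}")
            if name in _SIGMA_NAMES and not (0.0 < v < 10.0):
                raise ParameterError(f"{name} (%CV) must lie in (0, 10), got {v}")

    # -- access ------------------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return float(self.values[name])

    def __getattr__(self, name: str) -> float:
        values = object.__getattribute__(self, "values")
        if name in values:
            return float(values[name])
        raise AttributeError(name)

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def key(self) -> tuple:
        """Hashable identity used for simulation caching."""
        return (self.model,) + tuple(sorted(self.values.items()))

    def unit(self, name: str) -> str:
        return UNITS.get(name, "?")

    # -- derived constants (never free) ------------------------------------
    @property
    def k_in0(self) -> float:
        """CKD baseline proliferation rate forcing RBC steady state."""
        if self.model != "ckd":
            raise ParameterError("k_in0 is defined for the CKD model only")
        return self.rbc0 / (self.ampn * self.ampc * self.t_rbc)

    @property
    def ret0(self) -> float:
        """CKD baseline reticulocyte (and erythroblast) pool size."""
        return self.ampn * self.ampc * self.k_in0 * self.t_prec

    @property
    def k_stage(self) -> float:
        """CIA shared rate: k_prol = k_circ = k_tr = (N+1)/MTT."""
        if self.model != "cia":
            raise ParameterError("k_stage is defined for the CIA model only")
        return (self.n_transit + 1.0) / self.mtt

    @property
    def hgb0(self) -> float:
        """Baseline hemoglobin, g/dL (RBC0 * MCH / 10)."""
        return self.rbc0 * self.mch / 10.0

    @property
    def erfeb0(self) -> float:
        """On-curve circadian ERFE baseline at t = 0 ng/mL."""
        omega = 2.0 * math.pi / 24.0
        return self.rm + self.ra * math.cos(omega * (0.0 - self.t_peak))

    def sigma_frac(self, analyte: str) -> float:
        """Fractional proportional-error SD for an analyte (%CV / 100)."""
        name = f"sigma_{analyte.lower()}"
        if name not in self.values:
            raise ParameterError(f"no residual error parameter for analyte {analyte!r}")
        return self[name] / 100.0

    def erythroid_initial_state(self) -> np.ndarray:
        """Steady-state initials [A_P1, A_P2, A_P3, A_P4, A_RBC]."""
        if self.model == "ckd":
            k0, t = self.k_in0, self.t_prec
            return np.array(
                [k0 * t, self.ampn * k0 * t, self.ret0, self.ret0, self.rbc0]
            )
        return np.full(5, self.rbc0)

    # -- modification / io --------------------------------------------------
    def replace(self, **overrides: float) -> "ParameterSet":
        new = dict(self.values)
        for name, value in overrides.items():
            if name not in new:
                raise ParameterError(f"unknown parameter {name!r} for model {self.model!r}")
            new[name] = float(value)
        return ParameterSet(self.model, new)

    def to_dict(self) -> dict:
        return {"model": self.model, "values": dict(self.values)}

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, data: Mapping) -> "ParameterSet":
        try:
            return cls(str(data["model"]), {k: float(v) for k, v in data["values"].items()})
        except KeyError as exc:
            raise ParameterError(f"parameter file missing key {exc}") from exc


def load_parameters(source: str | Path | Mapping) -> ParameterSet:
    """Load a :class:`ParameterSet`.

    ``source`` may be the literal name ``"table1"`` (CKD estimates) or
    ``"table2"`` (CIA estimates), a YAML file path, or an already-parsed
    mapping with ``model``/``values`` keys.
    """
    if isinstance(source, Mapping):
        return ParameterSet.from_dict(source)
    name = str(source).lower()
    if name == "table1":
        return ParameterSet("ckd", dict(TABLE1))
    if name == "table2":
        return ParameterSet("cia", dict(TABLE2))
    path = Path(source)
    if not path.exists():
        raise ParameterError(
            f"parameter source {source!r} is neither 'table1'/'table2' nor an existing file"
        )
    return ParameterSet.from_dict(yaml.safe_load(path.read_text()))


# ---------------------------------------------------------------------------
# drug kinetics configuration

_PK_REQUIRED = {
    "rhuepo": ("vmax", "km", "kel", "kpt", "ktp", "vc"),
    "carboplatin": ("kel", "k12", "k21", "k13", "k31", "vc"),
}


def load_pk_config(path: str | Path | None = None) -> dict:
    """Load PK constants for rHuEPO and carboplatin.

    With ``path=None`` the packaged defaults are returned
    (``config/pk_defaults.yaml`` — synthetic placeholder values, see the
    file header and the methods note).
    """
    if path is None:
        path = Path(__file__).parent / "config" / "pk_defaults.yaml"
    cfg = yaml.safe_load(Path(path).read_text())
    for drug, names in _PK_REQUIRED.items():
        if drug not in cfg:
            raise ParameterError(f"PK config missing section {drug!r}")
        for name in names:
            v = cfg[drug].get(name)
            if v is None or not math.isfinite(float(v)) or float(v) < 0:
                raise ParameterError(f"PK config {drug}.{name} missing or invalid: {v!r}")
            cfg[drug][name] = float(v)
        if cfg[drug]["vc"] <= 0 or (drug == "rhuepo" and cfg[drug]["km"] <= 0):
            raise ParameterError(f"PK config {drug}: volumes and Km must be > 0")
    return cfg


def pk_key(pk_config: Mapping) -> tuple:
    """Hashable identity of a PK config (for simulation caching)."""
    out: list = []
    for drug in sorted(_PK_REQUIRED):
        for name in _PK_REQUIRED[drug]:
            out.append((drug, name, float(pk_config[drug][name])))
    return tuple(out)
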
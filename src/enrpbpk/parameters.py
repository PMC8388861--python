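"""Parameterization of the two-analyte pig PBPK model.

The model describes enrofloxacin (ENR) given orally to growing pigs and its
active metabolite ciprofloxacin (CIP), formed by hepatic metabolism.  All
compartments are flow-limited; tissue volumes and blood flows are derived
deterministically from body weight, so a single scalar (``BW``) perturbation
propagates through every scaled quantity.

Units
-----
* body weight ``BW`` — kg
* cardiac output coefficient ``QCC`` — L/h per kg**cardiac_exponent
* first-order rates (``Ka``, ``Kint``, ``Kst``) — 1/h
* clearance coefficients (``KmC``, ``KurineC``, ``Kurine1C``) — L/h per
  kg**clearance_exponent
* concentrations — mg/L == µg/mL == µg/g (tissue density taken as 1 g/mL)
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import yaml

TISSUES = ("liver", "kidney", "muscle", "fat", "rest")
"""Perfused tissue compartments (besides lung and blood)."""

EDIBLE_TISSUES = ("muscle", "fat", "liver", "kidney")
"""Tissues carrying a maximum residue limit."""

ANALYTES = ("ENR", "CIP")

_FLOW_TOL = 1e-9


class ParameterError(ValueError):
    """Raised when a parameter set violates its physical invariants."""


@dataclass
class PhysiologicalParams:
    """Pig physiology: body weight, cardiac output and organ fractions.

    ``flow_fractions`` are fractions of cardiac output for the perfused
    tissues and must sum to 1 (``rest`` closes the balance).
    ``volume_fractions`` are fractions of body weight and may sum to < 1
    (unperfused mass such as gut contents and bone mineral).
    """

    BW: float
    QCC: float
    flow_fractions: dict[str, float]
    volume_fractions: dict[str, float]
    cardiac_exponent: float = 0.75
    clearance_exponent: float = 0.75

    def __post_init__(self) -> None:
        if self.BW <= 0:
            raise ParameterError(f"BW must be positive, got {self.BW}")
        if self.QCC <= 0:
            raise ParameterError(f"QCC must be positive, got {self.QCC}")
        missing = set(TISSUES) - set(self.flow_fractions)
        if missing:
            raise ParameterError(f"flow_fractions missing tissues: {sorted(missing)}")
        missing = {"blood", "lung", *TISSUES} - set(self.volume_fractions)
        if missing:
            raise ParameterError(f"volume_fractions missing compartments: {sorted(missing)}")
        for name, frac in {**self.flow_fractions, **self.volume_fractions}.items():
            if not 0 < frac < 1:
                raise ParameterError(f"fraction {name}={frac} outside (0, 1)")
        flow_sum = sum(self.flow_fractions[t] for t in TISSUES)
        if abs(flow_sum - 1.0) > _FLOW_TOL:
            raise ParameterError(f"flow fractions sum to {flow_sum!r}, expected 1")
        vol_sum = sum(self.volume_fractions.values())
        if vol_sum > 1.0 + _FLOW_TOL:
            raise ParameterError(f"volume fractions sum to {vol_sum!r} > 1")

    @property
    def cardiac_output(self) -> float:
        """Total cardiac output QC in L/h."""
        return self.QCC * self.BW**self.cardiac_exponent

    def flow(self, tissue: str) -> float:
        """Blood flow to *tissue* in L/h."""
        return self.flow_fractions[tissue] * self.cardiac_output

    def volume(self, compartment: str) -> float:
        """Volume of *compartment* in L (density 1 kg/L)."""
        return self.volume_fractions[compartment] * self.BW


@dataclass
class ChemicalParams:
    """Chemical-specific constants for ENR and CIP.

    ``Frac`` is the mass fraction of hepatically cleared ENR that appears as
    CIP; the remainder goes to the unspecified-metabolite pool.  Partition
    coefficients are tissue:plasma ratios for the keys
    {liver, kidney, muscle, fat, lung, rest}.
    """

    Ka: float
    Kint: float
    Kst: float
    Frac: float
    KmC: float
    KurineC: float
    Kurine1C: float
    pc_enr: dict[str, float]
    pc_cip: dict[str, float]

    def __post_init__(self) -> None:
        for name in ("Ka", "Kint", "Kst", "KmC", "KurineC", "Kurine1C"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0 <= self.Frac <= 1:
            raise ParameterError(f"Frac must be in [0, 1], got {self.Frac}")
        for label, pcs in (("pc_enr", self.pc_enr), ("pc_cip", self.pc_cip)):
            missing = {"lung", *TISSUES} - set(pcs)
            if missing:
                raise ParameterError(f"{label} missing tissues: {sorted(missing)}")
            for tissue, pc in pcs.items():
                if pc <= 0:
                    raise ParameterError(f"{label}[{tissue}]={pc} must be > 0")


@dataclass
class DosingRegimen:
    """Repeated oral dosing: dose per administration and schedule.

    The default regimen is the label regimen for the granules:
    5 mg/kg b.w. twice daily for 5 days (10 doses 12 h apart), simulated to
    228 h so five days of post-treatment depletion are covered.
    """

    dose_mg_per_kg: float = 5.0
    interval_h: float = 12.0
    n_doses: int = 10
    t_end_h: float = 228.0

    def __post_init__(self) -> None:
        if self.dose_mg_per_kg < 0:
            raise ParameterError("dose must be >= 0")
        if self.interval_h <= 0:
            raise ParameterError("interval must be > 0")
        if self.n_doses < 1:
            raise ParameterError("n_doses must be >= 1")
        if self.t_end_h < (self.n_doses - 1) * self.interval_h:
            raise ParameterError(
                f"t_end_h={self.t_end_h} ends before the last dose at "
                f"{(self.n_doses - 1) * self.interval_h} h"
            )

    @property
    def dose_times(self) -> tuple[float, ...]:
        return tuple(i * self.interval_h for i in range(self.n_doses))

    @property
    def last_dose_time(self) -> float:
        """Time of the final administration; the withdrawal clock starts here."""
        return (self.n_doses - 1) * self.interval_h


@dataclass
class ModelParameters:
    """Complete model parameterization: physiology + chemistry + dosing."""

    physiology: PhysiologicalParams
    chemical: ChemicalParams
    dosing: DosingRegimen = field(default_factory=DosingRegimen)

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)

    # -- scalar parameter access by name (used by sensitivity / Monte Carlo) --

    def get(self, name: str) -> float:
        """Look up a scalar parameter by its conventional name.

        Recognised names: ``BW``, ``QCC``, rate/clearance coefficients, and
        partition coefficients in the compact field notation ``Pl, Pk, Pm,
        Pf, Plu, Pr`` for ENR and ``Pl1, Pk1, ...`` for CIP.
        """
        section, key = self._locate(name)
        if section is None:
            return getattr(*key)
        return section[key]

    def set(self, name: str, value: float) -> None:
        section, key = self._locate(name)
        if section is None:
            setattr(key[0], key[1], value)
        else:
            section[key] = value

    def _locate(self, name: str):
        phys, chem = self.physiology, self.chemical
        if name in ("BW", "QCC"):
            return None, (phys, name)
        if name in ("Ka", "Kint", "Kst", "Frac", "KmC", "KurineC", "Kurine1C"):
            return None, (chem, name)
        if name == "dose_mg_per_kg":
            return None, (self.dosing, name)
        pc = _PC_NAMES.get(name)
        if pc is not None:
            analyte, tissue = pc
            return (chem.pc_enr if analyte == "ENR" else chem.pc_cip), tissue
        raise ParameterError(f"unknown parameter name: {name!r}")

    @property
    def parameter_names(self) -> tuple[str, ...]:
        """All scalar names addressable via :meth:`get`/:meth:`set`."""
        return (
            "BW", "QCC", "Ka", "Kint", "Kst", "Frac", "KmC", "KurineC",
            "Kurine1C", *_PC_NAMES,
        )

    # ------------------------------- I/O -------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(
            physiology=PhysiologicalParams(**d["physiology"]),
            chemical=ChemicalParams(**d["chemical"]),
            dosing=DosingRegimen(**d.get("dosing", {})),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "ModelParameters":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


# compact field notation <-> (analyte, tissue)
_PC_NAMES: dict[str, tuple[str, str]] = {
    "Pl": ("ENR", "liver"), "Pk": ("ENR", "kidney"), "Pm": ("ENR", "muscle"),
    "Pf": ("ENR", "fat"), "Plu": ("ENR", "lung"), "Pr": ("ENR", "rest"),
    "Pl1": ("CIP", "liver"), "Pk1": ("CIP", "kidney"), "Pm1": ("CIP", "muscle"),
    "Pf1": ("CIP", "fat"), "Plu1": ("CIP", "lung"), "Pr1": ("CIP", "rest"),
}

PARTITION_COEFFICIENT_NAMES = tuple(_PC_NAMES)

CHEMICAL_PARAMETER_NAMES = (
    "Ka", "Kint", "Kst", "Frac", "KmC", "KurineC", "Kurine1C",
)


def default_parameters() -> ModelParameters:
    """The packaged default pig/ENR parameter set (55 kg grower pig)."""
    ref = resources.files("enrpbpk.data").joinpath("pig_enr_defaults.yaml")
    return ModelParameters.from_dict(yaml.safe_load(ref.read_text()))
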
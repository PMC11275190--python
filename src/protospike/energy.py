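"""Molecular-mechanics energy decomposition bookkeeping.

A force-field total energy splits into stretch, bend, stretch-bend, torsion,
non-1,4 van der Waals, 1,4 van der Waals and dipole-dipole terms (the last
five expanding the non-bonded and cross contributions). This module only
audits such ledgers — summing components and checking them against a stated
total — it performs no force-field evaluation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class EnergyDecomposition:
    """Energy components in kcal/mol, with an optional stated total."""

    stretch: float
    bend: float
    stretch_bend: float
    torsion: float
    non14_vdw: float
    vdw14: float
    dipole_dipole: float
    stated_total: float | None = None

    COMPONENT_FIELDS = ("stretch", "bend", "stretch_bend", "torsion",
                        "non14_vdw", "vdw14", "dipole_dipole")

    def __post_init__(self) -> None:
        for name in self.COMPONENT_FIELDS:
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValueError(f"component {name} must be a finite number")

    def components(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.COMPONENT_FIELDS}

    @classmethod
    def from_dict(cls, d: dict) -> "EnergyDecomposition":
        missing = [k for k in cls.COMPONENT_FIELDS if k not in d]
        if missing:
            raise ValueError(f"missing energy components: {missing}")
        return cls(**{k: float(d[k]) for k in cls.COMPONENT_FIELDS},
                   stated_total=(float(d["stated_total"])
                                 if d.get("stated_total") is not None else None))


#: published energy-minimisation ledger for the chloroform / L-Glu-L-Arg
#: dipeptide system (kcal/mol), used as the worked audit example.
GLU_ARG_CHLOROFORM = EnergyDecomposition(
    stretch=0.6971, bend=5.7351, stretch_bend=0.2346, torsion=-0.5590,
    non14_vdw=-9.7724, vdw14=7.9509, dipole_dipole=-14.7107,
    stated_total=-10.4245)


def total_energy(d: EnergyDecomposition) -> float:
    """Sum of the seven components (kcal/mol), compensated summation."""
    return math.fsum(d.components().values())


@dataclass(frozen=True)
class AuditResult:
    passed: bool
    total: float
    stated_total: float
    discrepancy: float
    tolerance: float


def audit(d: EnergyDecomposition, tolerance: float = 0.001) -> AuditResult:
    """Check |sum(components) - stated_total| <= tolerance.

    The default tolerance of 0.001 kcal/mol is one unit in the last printed
    decimal of a 4-decimal table. The discrepancy is reported either way.
    """
    if d.stated_total is None:
        raise ValueError("stated_total is required for an audit")
    total = total_energy(d)
    disc = abs(total - d.stated_total)
    return AuditResult(passed=bool(disc <= tolerance), total=total,
                       stated_total=d.stated_total, discrepancy=disc,
                       tolerance=tolerance)
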
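"""Binding free energy <-> inhibition constant thermodynamics.

Docking engines in the AutoDock family report, alongside the binding free
energy ΔG (kcal/mol), the inhibition constant

    Ki = exp(ΔG / (R T))

in molar units, with R = 1.98720425e-3 kcal mol^-1 K^-1 and T = 298.15 K.
This module converts in both directions (Ki expressed in nM) and verifies
reported docking tables against their own ΔG values.  Rounding ΔG to two
decimals propagates to roughly ±0.85% in Ki at room temperature, hence the
default 1% verification tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List

from .dataset_io import DockingRecord
from .errors import DomainError

__all__ = ["ThermoConfig", "ki_from_dg", "dg_from_ki", "verify_docking_table"]

GAS_CONSTANT_KCAL = 1.98720425e-3  # kcal / (mol K)


@dataclass(frozen=True)
class ThermoConfig:
    gas_constant: float = GAS_CONSTANT_KCAL
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise DomainError(f"temperature must be > 0 K, got {self.temperature}")
        if not self.gas_constant > 0:
            raise DomainError("gas constant must be > 0")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature


def ki_from_dg(dg: float, config: ThermoConfig = ThermoConfig()) -> float:
    """Inhibition constant in nM from a binding free energy in kcal/mol.

    ΔG = 0 maps to 1 M (1e9 nM); more negative ΔG gives smaller Ki.
    """
    if not math.isfinite(dg):
        raise DomainError(f"dg must be finite, got {dg}")
    return math.exp(dg / config.rt) * 1e9


def dg_from_ki(ki: float, config: ThermoConfig = ThermoConfig()) -> float:
    """Binding free energy in kcal/mol from an inhibition constant in nM.

    Exact inverse of :func:`ki_from_dg`.
    """
    if not (math.isfinite(ki) and ki > 0):
        raise DomainError(f"ki must be finite and > 0 nM, got {ki}")
    return config.rt * math.log(ki * 1e-9)


def verify_docking_table(
    records: Iterable[DockingRecord],
    config: ThermoConfig = ThermoConfig(),
    rel_tol: float = 0.01,
) -> List[dict]:
    """Recompute Ki from each record's ΔG and compare with the reported Ki.

    A row passes when |computed - reported| / reported <= rel_tol.
    """
    report = []
    for rec in records:
        computed = ki_from_dg(rec.binding_energy, config)
        rel_err = abs(computed - rec.reported_ki) / rec.reported_ki
        report.append(
            {
                "compound": rec.compound_id,
                "target": rec.target,
                "dg_kcalmol": rec.binding_energy,
                "reported_ki_nM": rec.reported_ki,
                "computed_ki_nM": computed,
                "rel_error": rel_err,
                "passed": rel_err <= rel_tol,
            }
        )
    return report
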
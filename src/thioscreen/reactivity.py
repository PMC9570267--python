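"""Conceptual-DFT global reactivity descriptors from frontier-orbital energies.

Within the Koopmans-style identification the vertical ionization potential
and electron affinity are read off the frontier orbitals,

    I = -E_HOMO,    A = -E_LUMO    (both converted from hartree to eV),

and the global descriptors follow:

    Eg    = I - A                 energy gap (eV)
    chi   = (I + A) / 2           electronegativity (eV)
    V     = -chi                  chemical potential (eV)
    eta   = (I - A) / 2           chemical hardness (eV)
    S     = 1 / (2 eta)           chemical softness (eV^-1)
    omega = chi^2 / (2 eta)       electrophilicity index (eV)
    N     = I_TCE - I             nucleophilicity index (eV)

The nucleophilicity scale is anchored at the ionization energy of
tetracyanoethylene (TCE).  That reference is not universal across codes;
here it is an empirical constant (default 4.21 eV, the value jointly
implied by the study tables — see :func:`calibrate_i_tce`), exposed as
configuration and carrying no physical endorsement.

All intermediates are kept at full precision; round only for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .dataset_io import QuantumRecord
from .errors import DomainError

__all__ = [
    "HARTREE_TO_EV",
    "DEFAULT_I_TCE",
    "GlobalDescriptors",
    "au_to_ev",
    "compute_global_descriptors",
    "calibrate_i_tce",
    "solvation_energy",
    "descriptor_table",
]

#: CODATA hartree -> electron-volt conversion used throughout.
HARTREE_TO_EV = 27.211386

#: Default nucleophilicity reference (ionization energy assigned to TCE), eV.
DEFAULT_I_TCE = 4.21


@dataclass(frozen=True)
class GlobalDescriptors:
    """The nine global reactivity descriptors, all in eV except softness (eV^-1)."""

    i_pot: float
    e_aff: float
    e_gap: float
    chi: float
    eta: float
    s_soft: float
    v_pot: float
    omega: float
    n_nuc: float


def au_to_ev(x: float) -> float:
    """Convert an energy from hartree (au) to eV."""
    return x * HARTREE_TO_EV


def compute_global_descriptors(
    e_homo: float, e_lumo: float, i_tce: float = DEFAULT_I_TCE
) -> GlobalDescriptors:
    """Compute all global reactivity descriptors from orbital energies in au.

    Parameters
    ----------
    e_homo, e_lumo : float
        Frontier-orbital energies in hartree; ``e_homo < e_lumo`` required
        (otherwise the hardness is non-positive and softness undefined).
    i_tce : float
        Nucleophilicity reference in eV.
    """
    if not e_homo < e_lumo:
        raise DomainError(
            f"require e_homo < e_lumo (eta > 0), got {e_homo} >= {e_lumo}"
        )
    i_pot = -au_to_ev(e_homo)
    e_aff = -au_to_ev(e_lumo)
    eta = (i_pot - e_aff) / 2.0
    chi = (i_pot + e_aff) / 2.0
    return GlobalDescriptors(
        i_pot=i_pot,
        e_aff=e_aff,
        e_gap=i_pot - e_aff,
        chi=chi,
        eta=eta,
        s_soft=1.0 / (2.0 * eta),
        v_pot=-chi,
        omega=chi * chi / (2.0 * eta),
        n_nuc=i_tce - i_pot,
    )


def calibrate_i_tce(rows: Sequence[Tuple[float, float]]) -> Tuple[float, float]:
    """Back out the nucleophilicity reference from (I, N) pairs.

    Since N = I_TCE - I, every row's ``n_nuc + i_pot`` is an estimate of
    I_TCE; returns the mean estimate and the maximum absolute residual
    about it (a self-consistency measure of the table).
    """
    rows = list(rows)
    if not rows:
        raise DomainError("calibrate_i_tce requires at least one (I, N) row")
    sums = [n + i for i, n in rows]
    estimate = sum(sums) / len(sums)
    residual = max(abs(s - estimate) for s in sums)
    return estimate, residual


def solvation_energy(e_total_gas: float, e_total_aq: float) -> float:
    """Aqueous-minus-gas total-energy difference, converted to eV.

    Negative values mean the solute is stabilized in water (the continuum
    solvation model lowers the total energy).
    """
    return au_to_ev(e_total_aq - e_total_gas)


def descriptor_table(
    records: Iterable[QuantumRecord],
    phase: str,
    i_tce: float = DEFAULT_I_TCE,
    compounds: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-compound global descriptors for one phase, as a DataFrame.

    Suspect records are excluded.  Rows appear in first-encounter order of
    the compounds (or in the order of an explicit ``compounds`` list, each
    of which must have a usable record).  Columns: compound, e_homo_au,
    e_lumo_au, then the nine descriptor fields.
    """
    usable = {}
    order: List[str] = []
    for rec in records:
        if rec.suspect or rec.phase != phase:
            continue
        if rec.e_homo is None or rec.e_lumo is None:
            continue
        if rec.compound_id not in usable:
            usable[rec.compound_id] = rec
            order.append(rec.compound_id)
    if compounds is not None:
        missing = [c for c in compounds if c not in usable]
        if missing:
            raise LookupError(
                f"no non-suspect {phase}-phase orbital record for: {missing}"
            )
        order = list(compounds)
    rows = []
    for cid in order:
        rec = usable[cid]
        d = compute_global_descriptors(rec.e_homo, rec.e_lumo, i_tce)
        rows.append(
            {
                "compound": cid,
                "e_homo_au": rec.e_homo,
                "e_lumo_au": rec.e_lumo,
                "i_pot": d.i_pot,
                "e_aff": d.e_aff,
                "e_gap": d.e_gap,
                "chi": d.chi,
                "eta": d.eta,
                "s_soft": d.s_soft,
                "v_pot": d.v_pot,
                "omega": d.omega,
                "n_nuc": d.n_nuc,
            }
        )
    columns = [
        "compound", "e_homo_au", "e_lumo_au", "i_pot", "e_aff", "e_gap",
        "chi", "eta", "s_soft", "v_pot", "omega", "n_nuc",
    ]
    return pd.DataFrame(rows, columns=columns)
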
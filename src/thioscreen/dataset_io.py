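"""Typed readers/writers for the tabular inputs and the bundled study tables.

Five CSV schemas are supported (exact headers):

``quantum``
    ``compound,phase[,e_total_au,dipole_D,e_homo_au,e_lumo_au,suspect]`` —
    total electronic energy (hartree) and dipole moment (debye), and/or
    frontier-orbital energies (hartree), per compound per phase.
``physchem``
    ``compound[,logp,mw_da,hbd,hba,n_rotb,psa_A2,logd74,pol_A3,mr_A3,vol_A3,sag_A2,he_kcalmol]``
``activity``
    ``compound,cell_line,ic50_uM`` — IC50 in µM; an empty cell is an
    explicitly missing measurement (never zero).
``docking``
    ``compound,target,dg_kcalmol,ki_nM,n_hbonds``
``bondlengths``
    ``parameter,experimental,<one column per method>`` — bond lengths in Å.

The bundled fixtures transcribe the study's printed tables cell for cell:
X-ray/computed bond lengths of the thiouracil nucleus, total energies and
dipoles of the 2H/6H/7H/9H derivatives in gas and aqueous phase,
frontier-orbital energies, physicochemical and SAR descriptors (with
etoposide as the reference drug), antiproliferative IC50 values over six
cell lines, and topoisomerase IIα/IIβ docking results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .errors import (
    FixtureLookupError,
    ParseError,
    SchemaError,
    ValidationError,
)

__all__ = [
    "QuantumRecord",
    "PhyschemRecord",
    "ActivityRecord",
    "DockingRecord",
    "BondLengthTable",
    "load_table",
    "bundled_fixture",
    "write_report",
    "fixture_names",
    "fixture_checksums",
]

PHASES = ("gas", "aqueous")
TARGETS = ("topo2a", "topo2b")


# --------------------------------------------------------------------------
# record types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class QuantumRecord:
    """Per-compound, per-phase electronic-structure summary.

    Energies are in hartree (au), the dipole moment in debye.  Either the
    total-energy pair or the orbital pair (or both) may be present; the
    orbital invariant ``e_homo < e_lumo`` is enforced whenever both
    orbitals are given.  ``suspect`` flags rows transcribed as printed but
    judged unreliable (a duplicated row in the source table); default
    loaders skip them.
    """

    compound_id: str
    phase: str
    e_total: Optional[float] = None
    dipole: Optional[float] = None
    e_homo: Optional[float] = None
    e_lumo: Optional[float] = None
    suspect: bool = False

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValidationError("compound_id must be non-empty")
        if self.phase not in PHASES:
            raise ValidationError(
                f"phase must be one of {PHASES}, got {self.phase!r}"
            )
        if self.e_homo is not None and self.e_lumo is not None:
            if not self.e_homo < self.e_lumo:
                raise ValidationError(
                    f"{self.compound_id}/{self.phase}: require e_homo < e_lumo, "
                    f"got {self.e_homo} >= {self.e_lumo}"
                )


@dataclass(frozen=True)
class PhyschemRecord:
    """ADME/SAR descriptor set for one compound.

    logP and logD(7.4) are dimensionless partition/distribution
    coefficients, MW in Da, PSA and surface-area grid in Å², polarizability,
    molar refractivity and molar volume in Å³, hydration energy in
    kcal/mol.  All property fields are optional so that partial tables
    (e.g. a SAR-only table) load under the same schema.
    """

    compound_id: str
    log_p: Optional[float] = None
    mw: Optional[float] = None
    hbd: Optional[int] = None
    hba: Optional[int] = None
    n_rotb: Optional[int] = None
    psa: Optional[float] = None
    log_d_74: Optional[float] = None
    polarizability: Optional[float] = None
    refractivity: Optional[float] = None
    volume: Optional[float] = None
    surface_area_grid: Optional[float] = None
    hydration_energy: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValidationError("compound_id must be non-empty")
        for name in ("hbd", "hba", "n_rotb"):
            v = getattr(self, name)
            if v is not None and (v < 0 or v != int(v)):
                raise ValidationError(
                    f"{self.compound_id}: {name} must be a non-negative integer, got {v}"
                )
        if self.mw is not None and not self.mw > 0:
            raise ValidationError(f"{self.compound_id}: mw must be > 0, got {self.mw}")
        if self.psa is not None and self.psa < 0:
            raise ValidationError(f"{self.compound_id}: psa must be >= 0, got {self.psa}")


@dataclass(frozen=True)
class ActivityRecord:
    """One IC50 measurement (µM) for a compound on a cell line.

    ``ic50 is None`` encodes not-tested/inactive — never zero.
    """

    compound_id: str
    cell_line: str
    ic50: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValidationError("compound_id must be non-empty")
        if not self.cell_line:
            raise ValidationError("cell_line must be non-empty")
        if self.ic50 is not None and not self.ic50 > 0:
            raise ValidationError(
                f"{self.compound_id}/{self.cell_line}: ic50 must be > 0 when present"
            )


@dataclass(frozen=True)
class DockingRecord:
    """Docking result against a topoisomerase II isoform.

    Binding free energy in kcal/mol (negative for a bound complex), the
    reported inhibition constant in nM, and the hydrogen-bond count.
    """

    compound_id: str
    target: str
    binding_energy: float
    reported_ki: float
    n_hbonds: int

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValidationError("compound_id must be non-empty")
        if self.target not in TARGETS:
            raise ValidationError(f"target must be one of {TARGETS}, got {self.target!r}")
        if not self.binding_energy < 0:
            raise ValidationError(
                f"{self.compound_id}: binding_energy must be < 0 for a reported complex"
            )
        if not self.reported_ki > 0:
            raise ValidationError(f"{self.compound_id}: reported_ki must be > 0")
        if self.n_hbonds < 0:
            raise ValidationError(f"{self.compound_id}: n_hbonds must be >= 0")


@dataclass(frozen=True)
class BondLengthTable:
    """Experimental vs computed bond lengths (Å) for a set of methods."""

    parameters: tuple
    experimental: tuple
    methods: dict  # method name -> tuple of lengths, insertion-ordered

    def __post_init__(self) -> None:
        n = len(self.parameters)
        if len(self.experimental) != n:
            raise ValidationError("experimental column length mismatch")
        for name, col in self.methods.items():
            if len(col) != n:
                raise ValidationError(f"method column {name!r} length mismatch")
        for col in (self.experimental, *self.methods.values()):
            if any(not v > 0 for v in col):
                raise ValidationError("all bond lengths must be > 0")


# --------------------------------------------------------------------------
# schema definitions: (required columns, optional columns)
# --------------------------------------------------------------------------

_SCHEMAS = {
    "quantum": (
        ["compound", "phase"],
        ["e_total_au", "dipole_D", "e_homo_au", "e_lumo_au", "suspect"],
    ),
    "physchem": (
        ["compound"],
        [
            "logp", "mw_da", "hbd", "hba", "n_rotb", "psa_A2", "logd74",
            "pol_A3", "mr_A3", "vol_A3", "sag_A2", "he_kcalmol",
        ],
    ),
    "activity": (["compound", "cell_line", "ic50_uM"], []),
    "docking": (["compound", "target", "dg_kcalmol", "ki_nM", "n_hbonds"], []),
    # bondlengths method columns are free-form; handled separately
    "bondlengths": (["parameter", "experimental"], None),
}

_MINUS_SIGN = "−"  # normalized to ASCII '-' on read


def _cell(raw: object, row: int, col: str, kind: type):
    """Parse one CSV cell; '' -> None; U+2212 normalized; errors carry row/col."""
    if raw is None:
        return None
    s = str(raw).strip().replace(_MINUS_SIGN, "-")
    if s == "":
        return None
    try:
        if kind is bool:
            if s.lower() in ("true", "1", "yes"):
                return True
            if s.lower() in ("false", "0", "no"):
                return False
            raise ValueError(s)
        if kind is int:
            return int(s)
        if kind is float:
            v = float(s)
            if not math.isfinite(v):
                raise ValueError(s)
            return v
        return s
    except ValueError as exc:
        raise ParseError(
            f"row {row}, column {col!r}: cannot parse {s!r} as {kind.__name__}"
        ) from exc


def _read_csv(path) -> pd.DataFrame:
    # keep_default_na=False so that '' is the only missing marker we honor
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def _check_header(df: pd.DataFrame, schema: str) -> None:
    required, optional = _SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{schema} table is missing required column(s) {missing}; "
            f"found columns {list(df.columns)}"
        )
    if optional is not None:
        unknown = [c for c in df.columns if c not in required + optional]
        if unknown:
            raise SchemaError(f"{schema} table has unknown column(s) {unknown}")


def load_table(path, schema: str):
    """Load and validate a CSV table under a named schema.

    Parameters
    ----------
    path : str or Path or file-like
        CSV source.
    schema : {'quantum', 'physchem', 'activity', 'docking', 'bondlengths'}

    Returns
    -------
    list of records (or a :class:`BondLengthTable` for ``bondlengths``),
    in file row order.
    """
    if schema not in _SCHEMAS:
        raise SchemaError(
            f"unknown schema {schema!r}; valid: {sorted(_SCHEMAS)}"
        )
    df = _read_csv(path)
    _check_header(df, schema)

    if schema == "bondlengths":
        params, exps, methods = [], [], {
            c: [] for c in df.columns if c not in ("parameter", "experimental")
        }
        if not methods:
            raise SchemaError("bondlengths table needs at least one method column")
        for i, row in enumerate(df.itertuples(index=False), start=1):
            d = dict(zip(df.columns, row))
            params.append(_cell(d["parameter"], i, "parameter", str))
            exps.append(_cell(d["experimental"], i, "experimental", float))
            for m in methods:
                methods[m].append(_cell(d[m], i, m, float))
        return BondLengthTable(
            parameters=tuple(params),
            experimental=tuple(exps),
            methods={m: tuple(v) for m, v in methods.items()},
        )

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = dict(zip(df.columns, row))
        get = lambda col, kind: _cell(d.get(col), i, col, kind)  # noqa: E731
        if schema == "quantum":
            rec = QuantumRecord(
                compound_id=get("compound", str) or "",
                phase=get("phase", str) or "",
                e_total=get("e_total_au", float),
                dipole=get("dipole_D", float),
                e_homo=get("e_homo_au", float),
                e_lumo=get("e_lumo_au", float),
                suspect=bool(get("suspect", bool)),
            )
        elif schema == "physchem":
            rec = PhyschemRecord(
                compound_id=get("compound", str) or "",
                log_p=get("logp", float),
                mw=get("mw_da", float),
                hbd=get("hbd", int),
                hba=get("hba", int),
                n_rotb=get("n_rotb", int),
                psa=get("psa_A2", float),
                log_d_74=get("logd74", float),
                polarizability=get("pol_A3", float),
                refractivity=get("mr_A3", float),
                volume=get("vol_A3", float),
                surface_area_grid=get("sag_A2", float),
                hydration_energy=get("he_kcalmol", float),
            )
        elif schema == "activity":
            rec = ActivityRecord(
                compound_id=get("compound", str) or "",
                cell_line=get("cell_line", str) or "",
                ic50=get("ic50_uM", float),
            )
        else:  # docking
            rec = DockingRecord(
                compound_id=get("compound", str) or "",
                target=get("target", str) or "",
                binding_energy=get("dg_kcalmol", float),
                reported_ki=get("ki_nM", float),
                n_hbonds=get("n_hbonds", int),
            )
        records.append(rec)
    return records


# --------------------------------------------------------------------------
# bundled fixtures
# --------------------------------------------------------------------------

_FIXTURES = {
    "bondlengths_tu": ("bondlengths_tu.csv", "bondlengths"),
    "energies_dipoles": ("energies_dipoles.csv", "quantum"),
    "reactivity_inputs": ("reactivity_inputs.csv", "quantum"),
    "physchem": ("physchem.csv", "physchem"),
    "sar_properties": ("sar_properties.csv", "physchem"),
    "activities": ("activities.csv", "activity"),
    "docking_alpha": ("docking_alpha.csv", "docking"),
    "docking_beta": ("docking_beta.csv", "docking"),
}


def fixture_names() -> tuple:
    """Names of the bundled study tables."""
    return tuple(sorted(_FIXTURES))


def _data_path(filename: str):
    return resources.files(__package__).joinpath("data", filename)


def bundled_fixture(name: str):
    """Return the transcription of one of the study's printed tables.

    Cells equal the printed values exactly (including their rounding).
    Valid names: bondlengths_tu, energies_dipoles, reactivity_inputs,
    physchem, sar_properties, activities, docking_alpha, docking_beta.
    """
    if name not in _FIXTURES:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; valid names: {', '.join(fixture_names())}"
        )
    filename, schema = _FIXTURES[name]
    with resources.as_file(_data_path(filename)) as p:
        return load_table(p, schema)


def fixture_checksums() -> dict:
    """SHA-256 digests of the bundled fixture files, as shipped and as found."""
    stored = json.loads(_data_path("checksums.json").read_text())
    actual = {}
    for filename, _ in _FIXTURES.values():
        actual[filename] = hashlib.sha256(
            _data_path(filename).read_bytes()
        ).hexdigest()
    return {"stored": stored, "actual": actual}


# --------------------------------------------------------------------------
# writing
# --------------------------------------------------------------------------

_WRITE_COLUMNS = {
    QuantumRecord: (
        "quantum",
        ["compound", "phase", "e_total_au", "dipole_D", "e_homo_au", "e_lumo_au", "suspect"],
        lambda r: [r.compound_id, r.phase, r.e_total, r.dipole, r.e_homo, r.e_lumo,
                   "true" if r.suspect else "false"],
    ),
    PhyschemRecord: (
        "physchem",
        ["compound", "logp", "mw_da", "hbd", "hba", "n_rotb", "psa_A2", "logd74",
         "pol_A3", "mr_A3", "vol_A3", "sag_A2", "he_kcalmol"],
        lambda r: [r.compound_id, r.log_p, r.mw, r.hbd, r.hba, r.n_rotb, r.psa,
                   r.log_d_74, r.polarizability, r.refractivity, r.volume,
                   r.surface_area_grid, r.hydration_energy],
    ),
    ActivityRecord: (
        "activity",
        ["compound", "cell_line", "ic50_uM"],
        lambda r: [r.compound_id, r.cell_line, r.ic50],
    ),
    DockingRecord: (
        "docking",
        ["compound", "target", "dg_kcalmol", "ki_nM", "n_hbonds"],
        lambda r: [r.compound_id, r.target, r.binding_energy, r.reported_ki, r.n_hbonds],
    ),
}


def _records_to_frame(records: Sequence) -> pd.DataFrame:
    if isinstance(records, BondLengthTable):
        data = {"parameter": records.parameters, "experimental": records.experimental}
        data.update({m: col for m, col in records.methods.items()})
        return pd.DataFrame(data)
    if len(records) == 0:
        raise ValidationError(
            "cannot infer schema from an empty collection; use write_report "
            "with schema= to write a header-only file"
        )
    kind = type(records[0])
    if kind not in _WRITE_COLUMNS:
        # generic result collection (dicts / dataclasses)
        rows = [
            dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
            for r in records
        ]
        return pd.DataFrame(rows)
    _, cols, torow = _WRITE_COLUMNS[kind]
    return pd.DataFrame([torow(r) for r in records], columns=cols)


def write_report(records, path, format: str = "csv", schema: Optional[str] = None):
    """Write records or results to CSV or JSON.

    Round-trip guarantee: ``load_table(write_report(x))`` reproduces ``x``
    field for field for the typed record collections.  An empty collection
    with an explicit ``schema`` writes a header-only CSV.
    """
    path = Path(path)
    if format not in ("csv", "json"):
        raise ValueError(f"format must be 'csv' or 'json', got {format!r}")
    if not isinstance(records, BondLengthTable) and len(records) == 0:
        if schema is None:
            raise ValidationError("empty collection requires an explicit schema")
        required, optional = _SCHEMAS[schema]
        cols = required + (optional or [])
        df = pd.DataFrame(columns=cols)
    else:
        df = _records_to_frame(records)
    try:
        if format == "csv":
            df.to_csv(path, index=False)
        else:
            df.to_json(path, orient="records", indent=1)
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc
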
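"""Multilinear-regression QSAR with IC50 response transforms.

The activity of a compound panel (IC50, µM) is modeled as a linear
function of molecular descriptors after one of four response transforms:

    identity            y = IC50
    reciprocal          y = 1 / IC50
    log10_reciprocal    y = log10(1 / IC50)   (the pIC50 convention)
    log10               y = log10(IC50)

Descriptors may be quantum (frontier-orbital energies in eV and the global
reactivity descriptors derived from them) or physicochemical (logP, PSA,
counts, ...).  Fits are ordinary least squares with an intercept; when the
system is rank-deficient or has at least as many parameters as
observations, the minimum-norm least-squares solution is returned and the
fit is flagged ``underdetermined`` — such fits interpolate exactly, so
their r² of 1 carries no predictive meaning and downstream reporting must
not treat it as validation.  Forward stepwise selection and
predicted-vs-observed tables round out the workflow.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .dataset_io import ActivityRecord, PhyschemRecord
from .errors import DimensionError, DomainError, SchemaError, ValidationError
from .reactivity import au_to_ev

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseTransform",
    "ModelSpec",
    "FittedModel",
    "transform_response",
    "inverse_transform",
    "descriptor_frame",
    "build_design_matrix",
    "fit_ols",
    "stepwise_forward",
    "apply_model",
    "r_squared",
    "predicted_vs_observed",
    "R2_ACCEPTANCE_GATE",
]

#: Models below this r² are not considered for validation.
R2_ACCEPTANCE_GATE = 0.6

#: Minimum r² improvement for forward selection to add a term.
STEPWISE_MIN_IMPROVEMENT = 1e-6


class ResponseTransform(str, enum.Enum):
    identity = "identity"
    reciprocal = "reciprocal"
    log10_reciprocal = "log10_reciprocal"
    log10 = "log10"


def transform_response(ic50, kind: ResponseTransform):
    """Apply a response transform to IC50 values in µM (scalar or array)."""
    kind = ResponseTransform(kind)
    x = np.asarray(ic50, dtype=float)
    if kind is not ResponseTransform.identity and np.any(x <= 0):
        raise DomainError(f"{kind.value} transform requires strictly positive IC50")
    if kind is ResponseTransform.identity:
        out = x
    elif kind is ResponseTransform.reciprocal:
        out = 1.0 / x
    elif kind is ResponseTransform.log10_reciprocal:
        out = -np.log10(x)
    else:
        out = np.log10(x)
    return float(out) if np.isscalar(ic50) else out


def inverse_transform(y, kind: ResponseTransform):
    """Map a response value back to the IC50 scale (µM)."""
    kind = ResponseTransform(kind)
    y = np.asarray(y, dtype=float)
    if kind is ResponseTransform.identity:
        out = y
    elif kind is ResponseTransform.reciprocal:
        if np.any(y == 0):
            raise DomainError("reciprocal inverse undefined at 0")
        out = 1.0 / y
    elif kind is ResponseTransform.log10_reciprocal:
        out = np.power(10.0, -y)
    else:
        out = np.power(10.0, y)
    return out


@dataclass(frozen=True)
class ModelSpec:
    """A QSAR model specification: response transform + named descriptors."""

    response: ResponseTransform
    descriptor_names: Tuple[str, ...]
    phase: str = "gas"

    def __post_init__(self) -> None:
        names = tuple(self.descriptor_names)
        if not names:
            raise ValidationError("descriptor_names must be non-empty")
        if len(set(names)) != len(names):
            raise ValidationError("descriptor names must be unique")
        object.__setattr__(self, "descriptor_names", names)
        object.__setattr__(self, "response", ResponseTransform(self.response))


@dataclass(frozen=True)
class FittedModel:
    """An OLS fit: intercept, named coefficients, and fit diagnostics.

    ``r2`` is clamped to [0, 1] for reporting; the raw value is kept in
    ``r2_raw``.  ``adj_r2`` is None when the residual degrees of freedom
    are non-positive.  ``std_errors`` are classical OLS standard errors
    (None for underdetermined fits, where they are undefined).
    """

    intercept: float
    coefficients: Dict[str, float]
    r2: float
    r2_raw: float
    adj_r2: Optional[float]
    n: int
    p: int
    underdetermined: bool
    predictions: np.ndarray
    std_errors: Optional[Dict[str, float]] = None
    intercept_se: Optional[float] = None

    def conf_int(self, alpha: float = 0.05) -> Dict[str, Tuple[float, float]]:
        """t-based confidence intervals for the named coefficients."""
        if self.std_errors is None:
            raise DomainError("confidence intervals undefined for this fit")
        from scipy import stats

        df = self.n - self.p - 1
        t = stats.t.ppf(1 - alpha / 2, df)
        return {
            name: (beta - t * self.std_errors[name], beta + t * self.std_errors[name])
            for name, beta in self.coefficients.items()
        }


# --------------------------------------------------------------------------
# descriptor resolution
# --------------------------------------------------------------------------

_PHYSCHEM_NAMES = {
    "logp": "log_p",
    "mw": "mw",
    "hbd": "hbd",
    "hba": "hba",
    "n_rotb": "n_rotb",
    "psa": "psa",
    "logd74": "log_d_74",
    "pol": "polarizability",
    "mr": "refractivity",
    "vol": "volume",
    "sag": "surface_area_grid",
    "he": "hydration_energy",
}

_QUANTUM_NAMES = (
    "e_homo", "e_lumo", "i_pot", "e_aff", "e_gap", "chi", "eta",
    "s_soft", "v_pot", "omega", "n_nuc",
)


def descriptor_frame(
    quantum: Optional[pd.DataFrame] = None,
    physchem: Optional[Iterable[PhyschemRecord]] = None,
) -> pd.DataFrame:
    """Merge quantum and physicochemical descriptors into one frame.

    ``quantum`` is a per-compound descriptor table (as produced by
    :func:`thioscreen.reactivity.descriptor_table`); orbital energies are
    re-expressed in eV under the names ``e_homo``/``e_lumo``.  Returns a
    DataFrame indexed by compound id; missing values are NaN.
    """
    frames = []
    if quantum is not None and len(quantum):
        q = quantum.set_index("compound")
        qd = pd.DataFrame(index=q.index)
        qd["e_homo"] = q["e_homo_au"].map(au_to_ev)
        qd["e_lumo"] = q["e_lumo_au"].map(au_to_ev)
        for name in _QUANTUM_NAMES[2:]:
            qd[name] = q[name]
        frames.append(qd)
    if physchem is not None:
        rows = {
            rec.compound_id: {
                pub: getattr(rec, attr) for pub, attr in _PHYSCHEM_NAMES.items()
            }
            for rec in physchem
        }
        if rows:
            frames.append(pd.DataFrame.from_dict(rows, orient="index"))
    if not frames:
        return pd.DataFrame()
    out = frames[0]
    for f in frames[1:]:
        out = out.join(f, how="outer")
    out.index.name = "compound"
    return out


def build_design_matrix(
    quantum: Optional[pd.DataFrame],
    physchem: Optional[Iterable[PhyschemRecord]],
    spec: ModelSpec,
    activities: Iterable[ActivityRecord],
    cell_line: str,
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Assemble (X, y, compound order) for one cell line.

    Rows are the compounds with an observed IC50 on ``cell_line`` (input
    order preserved); columns follow ``spec.descriptor_names``; the
    response vector is already transformed.  Compounds with missing IC50
    are dropped and logged.  Every named descriptor must resolve for every
    kept compound.
    """
    desc = descriptor_frame(quantum, physchem)
    valid = list(desc.columns)
    unknown = [n for n in spec.descriptor_names if n not in valid]
    if unknown:
        raise SchemaError(
            f"unresolvable descriptor name(s) {unknown}; valid names: {sorted(valid)}"
        )
    compounds, y = [], []
    for rec in activities:
        if rec.cell_line != cell_line:
            continue
        if rec.ic50 is None:
            logger.info("dropping %s on %s: IC50 missing", rec.compound_id, cell_line)
            continue
        compounds.append(rec.compound_id)
        y.append(rec.ic50)
    if not compounds:
        raise DomainError(f"no usable activity rows for cell line {cell_line!r}")
    missing_cmp = [c for c in compounds if c not in desc.index]
    if missing_cmp:
        raise SchemaError(f"no descriptors for compound(s) {missing_cmp}")
    X = desc.loc[compounds, list(spec.descriptor_names)].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = [
            (c, n)
            for c, row in zip(compounds, X)
            for n, v in zip(spec.descriptor_names, row)
            if np.isnan(v)
        ]
        raise SchemaError(f"descriptor value(s) missing: {bad}")
    y = transform_response(np.asarray(y, dtype=float), spec.response)
    return X, y, compounds


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot, clamped to [0, 1].

    A constant observed vector (SS_tot = 0) has no explainable variance
    and returns 0 by convention.
    """
    return min(1.0, max(0.0, _r2_raw(observed, predicted)))


def _r2_raw(observed, predicted) -> float:
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise DimensionError(f"shape mismatch: {o.shape} vs {p.shape}")
    if o.size < 2:
        raise DomainError("r_squared requires n >= 2")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0
    ss_res = float(np.sum((o - p) ** 2))
    return 1.0 - ss_res / ss_tot


def fit_ols(
    matrix: np.ndarray,
    response: np.ndarray,
    names: Optional[Sequence[str]] = None,
) -> FittedModel:
    """Least-squares fit with intercept; minimum-norm when underdetermined.

    For a full-rank overdetermined system this is ordinary OLS with
    classical standard errors.  When ``p + 1 >= n`` or the augmented
    matrix is rank-deficient, ``numpy.linalg.lstsq`` returns the
    minimum-norm solution, the fit is flagged ``underdetermined``, and
    standard errors / adjusted r² are undefined.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(response, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise DimensionError(f"incompatible shapes {X.shape} and {y.shape}")
    n, p = X.shape
    if n == 0:
        raise DomainError("fit_ols requires n >= 1")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValidationError("design matrix and response must be finite")
    if names is None:
        names = [f"x{j + 1}" for j in range(p)]
    names = list(names)
    if len(names) != p:
        raise DimensionError(f"{len(names)} names for {p} columns")

    A = np.hstack([np.ones((n, 1)), X])
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    underdetermined = (p + 1 >= n) or (rank < p + 1)
    yhat = A @ beta
    if n >= 2:
        raw = _r2_raw(y, yhat)
    else:
        raw = 1.0  # single observation: exact interpolation
    r2 = min(1.0, max(0.0, raw))
    dof = n - p - 1
    adj = None
    if dof > 0 and not underdetermined:
        adj = 1.0 - (1.0 - raw) * (n - 1) / dof

    std_errors = intercept_se = None
    if not underdetermined and dof > 0:
        resid = y - yhat
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(A.T @ A)
        se = np.sqrt(np.diag(cov))
        intercept_se = float(se[0])
        std_errors = {nm: float(se[j + 1]) for j, nm in enumerate(names)}

    return FittedModel(
        intercept=float(beta[0]),
        coefficients={nm: float(b) for nm, b in zip(names, beta[1:])},
        r2=r2,
        r2_raw=raw,
        adj_r2=adj,
        n=n,
        p=p,
        underdetermined=underdetermined,
        predictions=yhat,
        std_errors=std_errors,
        intercept_se=intercept_se,
    )


def stepwise_forward(
    candidates: Union[pd.DataFrame, Mapping[str, Sequence[float]]],
    response: np.ndarray,
    max_terms: int,
) -> Tuple[List[str], List[dict]]:
    """Greedy forward selection maximizing r² at each step.

    Stops when ``max_terms`` is reached, when no candidate improves r² by
    at least 1e-6, or when adding a term would make the fit
    underdetermined (p + 1 >= n).  Ties break by candidate order.
    Returns the selected names and a per-step trace.
    """
    if max_terms < 1:
        raise DomainError("max_terms must be >= 1")
    if not isinstance(candidates, pd.DataFrame):
        candidates = pd.DataFrame(dict(candidates))
    if candidates.shape[1] == 0:
        raise DomainError("candidate set must be non-empty")
    y = np.asarray(response, dtype=float)
    selected: List[str] = []
    trace: List[dict] = []
    best_r2 = 0.0
    n = len(y)
    while len(selected) < max_terms:
        if len(selected) + 2 >= n:  # next term would give p + 1 >= n
            break
        best = None
        for name in candidates.columns:
            if name in selected:
                continue
            X = candidates[list(selected) + [name]].to_numpy(dtype=float)
            fit = fit_ols(X, y, names=selected + [name])
            if best is None or fit.r2 > best[1]:
                best = (name, fit.r2)
        if best is None:
            break
        name, r2 = best
        improvement = r2 - best_r2
        if selected and improvement < STEPWISE_MIN_IMPROVEMENT:
            break
        if not selected and r2 < STEPWISE_MIN_IMPROVEMENT:
            break
        selected.append(name)
        best_r2 = r2
        trace.append({"step": len(selected), "added": name, "r2": r2})
    return selected, trace


def apply_model(
    intercept: float,
    coefficients: Mapping[str, float],
    rows: Union[pd.DataFrame, Sequence[Mapping[str, float]], Mapping[str, float]],
) -> np.ndarray:
    """Evaluate ``intercept + sum(coef * descriptor)`` on descriptor rows.

    Pure evaluation — no fitting.  ``rows`` may be a DataFrame, a sequence
    of mappings, or a single mapping (one row).
    """
    if isinstance(rows, Mapping):
        rows = [rows]
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(list(rows))
    missing = [k for k in coefficients if k not in rows.columns]
    if missing:
        raise SchemaError(f"descriptor(s) {missing} missing from rows")
    out = np.full(len(rows), float(intercept))
    for name, coef in coefficients.items():
        out = out + coef * rows[name].to_numpy(dtype=float)
    return out


def predicted_vs_observed(
    model: FittedModel,
    matrix: np.ndarray,
    response: np.ndarray,
    compounds: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Paired observed/predicted/residual table for reporting or plotting."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(response, dtype=float)
    if X.shape[0] == 0:
        raise DimensionError("empty design matrix")
    if X.shape[0] != y.shape[0] or X.shape[1] != model.p:
        raise DimensionError(
            f"model fitted with p={model.p} cannot score matrix {X.shape} / {y.shape}"
        )
    names = list(model.coefficients)
    pred = apply_model(model.intercept, model.coefficients, pd.DataFrame(X, columns=names))
    if compounds is None:
        compounds = [f"row{i + 1}" for i in range(len(y))]
    return pd.DataFrame(
        {
            "compound": list(compounds),
            "observed": y,
            "predicted": pred,
            "residual": y - pred,
        }
    )
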
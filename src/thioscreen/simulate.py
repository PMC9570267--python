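"""Synthetic compound panels with the statistical structure QSAR assumes.

The generator draws frontier-orbital energies and physicochemical
descriptors uniformly over plausibility ranges bracketing the study panel
(printed min/max padded by ~10%), derives the global reactivity
descriptors from the orbitals — so every descriptor identity (S·η = 1/2,
Eg = I − A, V = −χ) holds by construction — and generates activities from
a known linear model on a chosen descriptor subset plus Gaussian noise on
the transformed-response scale:

    y = intercept + Σ βj · descriptor_j + ε,   ε ~ N(0, σ²)
    IC50 = inverse_transform(y)

Log-family transforms guarantee positive IC50; for the identity and
reciprocal kinds the noise is rejection-resampled per compound until the
implied IC50 is positive.  A censor fraction marks round(n·fraction)
activities as missing, emulating the not-tested cells of real panels.
The same seed always reproduces byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import qsar, reactivity
from .dataset_io import load_table
from .errors import DomainError, ValidationError
from .qsar import ResponseTransform

__all__ = ["SimulationConfig", "simulate_compounds", "recovery_experiment"]

# uniform plausibility ranges; orbital ranges in hartree, the rest in the
# units of the physchem schema.  Integer-valued descriptors noted below.
DEFAULT_RANGES: Dict[str, Tuple[float, float]] = {
    "e_homo": (-0.26, -0.19),
    "e_lumo": (-0.13, -0.09),
    "e_total": (-1700.0, -1400.0),
    "dipole": (6.0, 16.0),
    "logp": (-3.0, 2.1),
    "mw": (355.0, 407.0),
    "hbd": (1, 5),
    "hba": (3, 7),
    "n_rotb": (0, 4),
    "psa": (66.0, 118.0),
    "logd74": (2.0, 2.6),
    "pol": (40.4, 46.4),
    "mr": (100.4, 117.7),
    "vol": (707.0, 1104.0),
    "sag": (547.0, 628.0),
    "he": (-17.3, -9.6),
}

_INTEGER_DESCRIPTORS = ("hbd", "hba", "n_rotb")

_MAX_REJECTION_TRIES = 1000


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped synthetic panel configuration.

    The default true model is a three-descriptor pIC50 relation
    (log10_reciprocal response) with residual noise sigma = 0.1 response
    units, the residual scale a well-behaved small-molecule QSAR would
    show; ranges default to the study panel's printed spreads.
    """

    n_compounds: int = 40
    seed: int = 0
    ranges: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    true_intercept: float = 0.5
    true_coefficients: Dict[str, float] = field(
        default_factory=lambda: {"logp": 0.8, "e_gap": -0.6, "hbd": 0.3}
    )
    response: ResponseTransform = ResponseTransform.log10_reciprocal
    noise_sigma: float = 0.1
    censor_fraction: float = 0.0
    cell_line: str = "SYN"
    i_tce: float = reactivity.DEFAULT_I_TCE

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValidationError("n_compounds must be >= 1")
        if not 0 <= self.censor_fraction < 1:
            raise ValidationError("censor_fraction must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        for name, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValidationError(f"range for {name!r} must have low < high")
        if not self.true_coefficients:
            raise ValidationError("true model needs at least one coefficient")
        object.__setattr__(self, "response", ResponseTransform(self.response))


def _draw(rng: np.random.Generator, cfg: SimulationConfig, name: str, n: int):
    lo, hi = cfg.ranges[name]
    if name in _INTEGER_DESCRIPTORS:
        return rng.integers(int(lo), int(hi) + 1, size=n)
    return rng.uniform(lo, hi, size=n)


def simulate_compounds(
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (quantum, physchem, activity) tables for one synthetic panel.

    The frames use the package CSV schemas, so they round-trip through
    :func:`thioscreen.dataset_io.load_table` unchanged.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_compounds
    ids = [f"S{i + 1:03d}" for i in range(n)]

    e_homo = _draw(rng, config, "e_homo", n)
    e_lumo = _draw(rng, config, "e_lumo", n)
    # default ranges are disjoint; guard against overlapping custom ranges
    bad = e_homo >= e_lumo
    while bad.any():
        e_homo[bad] = rng.uniform(*config.ranges["e_homo"], size=int(bad.sum()))
        bad = e_homo >= e_lumo

    quantum = pd.DataFrame(
        {
            "compound": ids,
            "phase": "gas",
            "e_total_au": _draw(rng, config, "e_total", n),
            "dipole_D": _draw(rng, config, "dipole", n),
            "e_homo_au": e_homo,
            "e_lumo_au": e_lumo,
            "suspect": "false",
        }
    )
    physchem = pd.DataFrame(
        {
            "compound": ids,
            "logp": _draw(rng, config, "logp", n),
            "mw_da": _draw(rng, config, "mw", n),
            "hbd": _draw(rng, config, "hbd", n),
            "hba": _draw(rng, config, "hba", n),
            "n_rotb": _draw(rng, config, "n_rotb", n),
            "psa_A2": _draw(rng, config, "psa", n),
            "logd74": _draw(rng, config, "logd74", n),
            "pol_A3": _draw(rng, config, "pol", n),
            "mr_A3": _draw(rng, config, "mr", n),
            "vol_A3": _draw(rng, config, "vol", n),
            "sag_A2": _draw(rng, config, "sag", n),
            "he_kcalmol": _draw(rng, config, "he", n),
        }
    )

    desc = _descriptor_frame(quantum, physchem, config.i_tce)
    unknown = [k for k in config.true_coefficients if k not in desc.columns]
    if unknown:
        raise ValidationError(
            f"true-model descriptor(s) {unknown} not generated; "
            f"valid names: {sorted(desc.columns)}"
        )
    eta_lin = config.true_intercept + sum(
        beta * desc[name].to_numpy(dtype=float)
        for name, beta in config.true_coefficients.items()
    )
    noise = rng.normal(0.0, config.noise_sigma, size=n)
    y = eta_lin + noise
    ic50 = np.asarray(qsar.inverse_transform(y, config.response), dtype=float)
    if config.response in (ResponseTransform.identity, ResponseTransform.reciprocal):
        for i in range(n):
            tries = 0
            while ic50[i] <= 0:
                tries += 1
                if tries > _MAX_REJECTION_TRIES:
                    raise DomainError(
                        "cannot generate positive IC50 under this true model; "
                        "adjust intercept/coefficients or use a log transform"
                    )
                y[i] = eta_lin[i] + rng.normal(0.0, config.noise_sigma)
                ic50[i] = float(qsar.inverse_transform(y[i], config.response))

    n_censor = int(round(n * config.censor_fraction))
    censored = set(rng.choice(n, size=n_censor, replace=False).tolist())
    activity = pd.DataFrame(
        {
            "compound": ids,
            "cell_line": config.cell_line,
            "ic50_uM": [
                "" if i in censored else repr(float(v)) for i, v in enumerate(ic50)
            ],
        }
    )
    return quantum, physchem, activity


def _descriptor_frame(quantum: pd.DataFrame, physchem: pd.DataFrame, i_tce: float):
    """Resolve the merged named-descriptor frame from schema-shaped tables."""
    import io as _io

    qrecs = load_table(_io.StringIO(quantum.to_csv(index=False)), "quantum")
    precs = load_table(_io.StringIO(physchem.to_csv(index=False)), "physchem")
    qtable = reactivity.descriptor_table(qrecs, phase="gas", i_tce=i_tce)
    return qsar.descriptor_frame(qtable, precs)


def recovery_experiment(config: SimulationConfig, replicates: int) -> dict:
    """Monte-Carlo coefficient-recovery study for the QSAR fitter.

    Runs ``replicates`` independent panels (seed of replicate r is
    ``config.seed + r``), refits the true descriptor set each time, and
    summarizes per-coefficient bias, RMSE, and empirical 95% CI coverage.
    """
    if replicates < 1:
        raise DomainError("replicates must be >= 1")
    p = len(config.true_coefficients)
    if p + 1 >= config.n_compounds:
        raise DomainError(
            f"underdetermined configuration (p + 1 = {p + 1} >= n = "
            f"{config.n_compounds}); increase n_compounds"
        )
    names = list(config.true_coefficients)
    true = np.array([config.true_coefficients[k] for k in names])
    estimates = np.empty((replicates, p))
    covered = np.zeros((replicates, p), dtype=bool)
    for r in range(replicates):
        cfg = SimulationConfig(
            n_compounds=config.n_compounds,
            seed=config.seed + r,
            ranges=config.ranges,
            true_intercept=config.true_intercept,
            true_coefficients=config.true_coefficients,
            response=config.response,
            noise_sigma=config.noise_sigma,
            censor_fraction=config.censor_fraction,
            cell_line=config.cell_line,
            i_tce=config.i_tce,
        )
        quantum, physchem, activity = simulate_compounds(cfg)
        desc = _descriptor_frame(quantum, physchem, cfg.i_tce)
        present = activity["ic50_uM"] != ""
        ids = activity.loc[present, "compound"].tolist()
        ic50 = activity.loc[present, "ic50_uM"].astype(float).to_numpy()
        y = qsar.transform_response(ic50, cfg.response)
        X = desc.loc[ids, names].to_numpy(dtype=float)
        fit = qsar.fit_ols(X, y, names=names)
        estimates[r] = [fit.coefficients[k] for k in names]
        if fit.std_errors is not None:
            ci = fit.conf_int(alpha=0.05)
            covered[r] = [ci[k][0] <= t <= ci[k][1] for k, t in zip(names, true)]
    bias = estimates.mean(axis=0) - true
    rmse = np.sqrt(((estimates - true) ** 2).mean(axis=0))
    coverage = covered.mean(axis=0)
    return {
        "names": names,
        "true": true.tolist(),
        "bias": bias.tolist(),
        "rmse": rmse.tolist(),
        "coverage": coverage.tolist(),
        "replicates": replicates,
        "n_compounds": config.n_compounds,
        "noise_sigma": config.noise_sigma,
    }
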
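"""Drug-likeness rule engines: Lipinski, Veber, and the Golden Triangle.

Lipinski's rule of five (inclusive thresholds): logP <= 5, MW <= 500 Da,
H-bond donors <= 5, H-bond acceptors <= 10; a compound passes with at most
one violation.  Veber's oral-bioavailability criteria (strict, "under"):
rotatable bonds < 10 and (T)PSA < 140 Å².  The Golden Triangle is a
triangular region of the (logD7.4, MW) plane — conventionally with base
from (-2, 200) to (5, 200) and apex (1.5, 450) — inside which compounds
tend to combine good permeability with metabolic stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

from .dataset_io import PhyschemRecord
from .errors import ConfigurationError, ValidationError

__all__ = [
    "RuleResult",
    "TrianglePolicy",
    "DEFAULT_TRIANGLE",
    "lipinski",
    "veber",
    "golden_triangle",
    "screen",
]


@dataclass(frozen=True)
class RuleResult:
    """Outcome of one rule set for one compound."""

    compound_id: str
    criteria: Dict[str, bool]
    passed: bool

    @property
    def score(self) -> int:
        return sum(self.criteria.values())


@dataclass(frozen=True)
class TrianglePolicy:
    """Triangle geometry in the (logD7.4, MW) plane."""

    vertices: Tuple[Tuple[float, float], ...] = ((-2.0, 200.0), (5.0, 200.0), (1.5, 450.0))
    boundary_inclusive: bool = True

    def __post_init__(self) -> None:
        if len(self.vertices) != 3:
            raise ConfigurationError("a triangle needs exactly three vertices")
        (x1, y1), (x2, y2), (x3, y3) = self.vertices
        # twice the signed area; zero means collinear
        if (x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1) == 0:
            raise ConfigurationError("triangle vertices are collinear")


DEFAULT_TRIANGLE = TrianglePolicy()


def lipinski(log_p: float, mw: float, hbd: int, hba: int,
             compound_id: str = "") -> RuleResult:
    """Apply Lipinski's rule of five (inclusive thresholds, fail on >1 violation)."""
    if not mw > 0:
        raise ValidationError(f"{compound_id or 'compound'}: mw must be > 0")
    if hbd < 0 or hba < 0:
        raise ValidationError(f"{compound_id or 'compound'}: counts must be >= 0")
    criteria = {
        "logp_le_5": log_p <= 5,
        "mw_le_500": mw <= 500,
        "hbd_le_5": hbd <= 5,
        "hba_le_10": hba <= 10,
    }
    violations = 4 - sum(criteria.values())
    return RuleResult(compound_id=compound_id, criteria=criteria, passed=violations <= 1)


def veber(n_rotb: int, tpsa: float, compound_id: str = "") -> RuleResult:
    """Apply Veber's criteria (strict inequalities: values must be *under* the caps)."""
    if n_rotb < 0 or tpsa < 0:
        raise ValidationError(f"{compound_id or 'compound'}: inputs must be >= 0")
    criteria = {
        "n_rotb_lt_10": n_rotb < 10,
        "tpsa_lt_140": tpsa < 140,
    }
    return RuleResult(
        compound_id=compound_id, criteria=criteria, passed=all(criteria.values())
    )


def _side(p, a, b) -> float:
    # z-component of (b - a) x (p - a)
    return (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])


def golden_triangle(log_d: float, mw: float,
                    policy: TrianglePolicy = DEFAULT_TRIANGLE) -> str:
    """Classify a point of the (logD7.4, MW) plane as 'inside' or 'outside'.

    Point-in-triangle by the sign-consistent half-plane test; boundary
    points count as inside when the policy is boundary-inclusive.
    """
    if not mw > 0:
        raise ValidationError("mw must be > 0")
    p = (log_d, mw)
    a, b, c = policy.vertices
    sides = (_side(p, a, b), _side(p, b, c), _side(p, c, a))
    if policy.boundary_inclusive:
        inside = all(s >= 0 for s in sides) or all(s <= 0 for s in sides)
    else:
        inside = all(s > 0 for s in sides) or all(s < 0 for s in sides)
    return "inside" if inside else "outside"


def _require(rec: PhyschemRecord, fields: List[str]) -> None:
    for f in fields:
        if getattr(rec, f) is None:
            raise ValidationError(
                f"compound {rec.compound_id!r}: field {f!r} is required for screening"
            )


def screen(physchem: Iterable[PhyschemRecord],
           policy: TrianglePolicy = DEFAULT_TRIANGLE) -> List[dict]:
    """Run all three rule sets over a compound panel.

    Returns one dict per compound, in input order, with the Lipinski and
    Veber results and the triangle class.
    """
    report = []
    for rec in physchem:
        _require(rec, ["log_p", "mw", "hbd", "hba", "n_rotb", "psa", "log_d_74"])
        lip = lipinski(rec.log_p, rec.mw, rec.hbd, rec.hba, rec.compound_id)
        veb = veber(rec.n_rotb, rec.psa, rec.compound_id)
        tri = golden_triangle(rec.log_d_74, rec.mw, policy)
        report.append(
            {
                "compound": rec.compound_id,
                "lipinski_score": lip.score,
                "lipinski_passed": lip.passed,
                "lipinski_criteria": dict(lip.criteria),
                "veber_passed": veb.passed,
                "veber_criteria": dict(veb.criteria),
                "golden_triangle": tri,
            }
        )
    return report
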
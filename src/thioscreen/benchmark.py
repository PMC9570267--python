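"""Geometry-accuracy benchmarking of quantum-chemistry methods.

A method's accuracy against X-ray bond lengths is summarized by the
percentage mean absolute deviation

    A% = 100 * mean(|computed_i - experimental_i|) / mean(experimental_i),

i.e. the mean absolute deviation normalized by the mean experimental bond
length.  Methods are then ranked ascending in A%; the smallest value marks
the level of theory that best reproduces the crystallographic geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .dataset_io import BondLengthTable
from .errors import DimensionError, DomainError

__all__ = ["BenchmarkResult", "mad_percent", "rank_methods"]


@dataclass(frozen=True)
class BenchmarkResult:
    method: str
    a_percent: float
    n_parameters: int


def mad_percent(computed: Sequence[float], experimental: Sequence[float]) -> float:
    """Percentage mean absolute deviation of ``computed`` from ``experimental``.

    Both inputs are bond lengths in Å (any common unit works: the metric is
    scale-invariant).  Returns 0 iff the columns agree element-wise.
    """
    c = np.asarray(computed, dtype=float)
    e = np.asarray(experimental, dtype=float)
    if c.shape != e.shape or c.ndim != 1:
        raise DimensionError(
            f"computed and experimental must be 1-D of equal length, "
            f"got shapes {c.shape} and {e.shape}"
        )
    if c.size == 0:
        raise DomainError("mad_percent requires at least one bond")
    if not (np.all(c > 0) and np.all(e > 0)):
        raise DomainError("bond lengths must be > 0")
    return float(100.0 * np.mean(np.abs(c - e)) / np.mean(e))


def rank_methods(table: BondLengthTable) -> List[BenchmarkResult]:
    """Rank the method columns of a bond-length table ascending in A%.

    The sort is stable: ties keep the table's column order.
    """
    if not table.methods:
        raise DomainError("table has no method columns")
    results = [
        BenchmarkResult(
            method=name,
            a_percent=mad_percent(col, table.experimental),
            n_parameters=len(col),
        )
        for name, col in table.methods.items()
    ]
    return sorted(results, key=lambda r: r.a_percent)
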
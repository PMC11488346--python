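"""Effective score / effective percentage neighborhood statistics.

For a pair of phenotypes (a "central" and a "surrounding" type) and a fixed
radius r (20 µm by default — the standard interaction distance for cell-cell
contact analysis), the two statistics are

    ES = (number of surrounding cells within r of central cells)
         / (number of central cells)

    EP = (number of central cells with >= 1 surrounding cell within r)
         / (number of central cells)

Higher values mean the two cell types are more closely co-distributed. The ES
numerator is ambiguous when one surrounding cell sits within r of several
central cells; two counting modes are provided and should be reported
side-by-side when it matters:

``sum_neighbors`` (default)
    Every (central, surrounding) pair within r counts once, so ES is the mean
    neighbor count per central cell. Under complete spatial randomness with
    surrounding intensity λ this has the closed-form expectation λ·π·r².
``unique_neighbors``
    Each surrounding cell counts at most once (the number of *distinct*
    surrounding cells within r of at least one central cell), so
    ES <= n_surrounding / n_central.

Distances are Euclidean centroid-to-centroid and the radius is inclusive
(a cell at exactly r is a neighbor). A cell is never its own neighbor when
central == surrounding. No edge correction is applied by default; a torus
boundary mode exists so that closed-form expectations are exact on simulated
windows. When there are no central cells the metrics are *undefined* and an
:class:`~spatprox.errors.UndefinedMetricError` is raised — callers (see
:func:`proximity_matrix`) propagate NaN, never 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .celltable import CellTable, phenotype_counts
from .errors import UndefinedMetricError, ValidationError

COUNTING_MODES = ("sum_neighbors", "unique_neighbors")
BOUNDARY_MODES = ("none", "torus")


@dataclass(frozen=True)
class ProximityQuery:
    """One (central, surrounding, radius) proximity question.

    ``window`` (width, height in µm) is required when ``boundary="torus"``;
    coordinates are then wrapped into [0, width) x [0, height) before the
    periodic neighbor search.
    """

    central: str
    surrounding: str
    radius: float = 20.0
    counting_mode: str = "sum_neighbors"
    boundary: str = "none"
    window: Optional[tuple] = None

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValidationError(f"radius must be > 0, got {self.radius}")
        if self.counting_mode not in COUNTING_MODES:
            raise ValidationError(f"unknown counting_mode: {self.counting_mode}")
        if self.boundary not in BOUNDARY_MODES:
            raise ValidationError(f"unknown boundary mode: {self.boundary}")
        if self.boundary == "torus" and self.window is None:
            raise ValidationError("torus boundary requires a window")


@dataclass
class NeighborCounts:
    """Per-central-cell counts of surrounding-type cells within the radius."""

    counts: np.ndarray          # int array, one entry per central cell
    n_central: int
    n_surrounding: int
    n_unique_surrounding: int   # distinct surrounding cells near >=1 central


@dataclass
class ProximityResult:
    query: ProximityQuery
    es: float
    ep: float
    neighbor_counts: Optional[NeighborCounts] = None


def _phenotype_coords(table: CellTable, phenotype: str) -> np.ndarray:
    mask = (table.cells["phenotype"] == phenotype).to_numpy()
    return table.coords[mask]


def count_neighbors(table: CellTable, query: ProximityQuery) -> NeighborCounts:
    """Count, for each central-type cell, the surrounding-type cells within
    the query radius (inclusive), excluding the cell itself when the two
    phenotypes coincide.

    Raises :class:`UndefinedMetricError` when the table holds no central cells.
    """
    central = _phenotype_coords(table, query.central)
    surrounding = _phenotype_coords(table, query.surrounding)
    if len(central) == 0:
        raise UndefinedMetricError(
            f"no {query.central!r} cells in sample {table.meta.sample_id!r}: "
            "ES/EP undefined")
    same = query.central == query.surrounding
    if len(surrounding) == 0:
        counts = np.zeros(len(central), dtype=int)
        return NeighborCounts(counts, len(central), 0, 0)

    boxsize = None
    if query.boundary == "torus":
        boxsize = np.asarray(query.window, dtype=float)
        central = np.mod(central, boxsize)
        surrounding = np.mod(surrounding, boxsize)
    tree = cKDTree(surrounding, boxsize=boxsize)
    neighbor_lists = tree.query_ball_point(central, query.radius)
    counts = np.fromiter((len(nb) for nb in neighbor_lists), dtype=int,
                         count=len(central))
    if same:
        # each central cell finds itself at distance 0; duplicates at the same
        # coordinates remain distinct cells and are kept
        counts -= 1
    unique = set()
    if same:
        # j counts iff some central cell other than j itself has it in range
        for i, nb in enumerate(neighbor_lists):
            unique.update(j for j in nb if j != i)
    else:
        for nb in neighbor_lists:
            unique.update(nb)
    return NeighborCounts(counts, len(central), len(surrounding), len(unique))


def effective_score(counts: NeighborCounts, mode: str = "sum_neighbors") -> float:
    """ES = surrounding-cell count / central-cell count, under the given
    counting mode (see module docstring)."""
    if counts.n_central == 0:
        raise UndefinedMetricError("no central cells: ES undefined")
    if mode == "sum_neighbors":
        return float(counts.counts.sum()) / counts.n_central
    if mode == "unique_neighbors":
        return float(counts.n_unique_surrounding) / counts.n_central
    raise ValidationError(f"unknown counting_mode: {mode}")


def effective_percentage(counts: NeighborCounts) -> float:
    """EP = fraction of central cells with at least one surrounding-type
    neighbor within the radius; always in [0, 1]."""
    if counts.n_central == 0:
        raise UndefinedMetricError("no central cells: EP undefined")
    return float((counts.counts > 0).mean())


def proximity(table: CellTable, query: ProximityQuery) -> ProximityResult:
    """Convenience wrapper: neighbor counts plus ES and EP for one query."""
    nc = count_neighbors(table, query)
    return ProximityResult(query=query,
                           es=effective_score(nc, query.counting_mode),
                           ep=effective_percentage(nc),
                           neighbor_counts=nc)


def cell_density(table: CellTable, phenotype: str, area_mm2: float) -> float:
    """Cells of the phenotype per mm² of annotated area."""
    if not area_mm2 > 0:
        raise ValidationError(f"area must be > 0 mm², got {area_mm2}")
    n = phenotype_counts(table).get(phenotype, 0)
    return n / area_mm2


def phenotype_ratio(table: CellTable, numerator: str, denominator: str) -> float:
    """Abundance ratio between two phenotypes (NaN when the denominator is absent)."""
    counts = phenotype_counts(table)
    denom = counts.get(denominator, 0)
    if denom == 0:
        return float("nan")
    return counts.get(numerator, 0) / denom


def proximity_matrix(table: CellTable, phenotypes, radius: float = 20.0,
                     counting_mode: str = "sum_neighbors",
                     boundary: str = "none", window=None) -> dict:
    """ES/EP for every ordered (central, surrounding) phenotype pair.

    Returns a dict keyed by ``(central, surrounding)``. The matrix is not
    symmetric — ES(A→B) normalizes by the A count, ES(B→A) by the B count.
    Diagonal entries are computed with self-exclusion. Pairs whose central
    phenotype is absent get ``es = ep = NaN`` (the undefined-metric value is
    propagated as missing, never as 0).
    """
    phenotypes = list(phenotypes)
    if len(phenotypes) < 2:
        raise ValidationError("need at least 2 phenotypes")
    out = {}
    for central in phenotypes:
        for surrounding in phenotypes:
            q = ProximityQuery(central=central, surrounding=surrounding,
                               radius=radius, counting_mode=counting_mode,
                               boundary=boundary, window=window)
            try:
                out[(central, surrounding)] = proximity(table, q)
            except UndefinedMetricError:
                out[(central, surrounding)] = ProximityResult(
                    query=q, es=float("nan"), ep=float("nan"))
    return out
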
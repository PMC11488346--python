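"""Synthetic tissue generator: point-process cell tables with known structure.

Real multiplex-immunofluorescence slides give phenotype-labelled centroid
tables with unknown generative structure; this module produces the same kind
of table from point processes whose spatial structure is known exactly, so
every proximity statistic can be tested against ground truth:

* **CSR** (complete spatial randomness): independent homogeneous Poisson
  patterns per phenotype — the null model. Under CSR the expected effective
  score at radius r against a surrounding intensity λ is λ·π·r², and the
  expected effective percentage is 1 − exp(−λ·π·r²).
* **Attraction** (Thomas cluster process): Poisson parents of one phenotype,
  each spawning a Poisson(µ) number of offspring of a second phenotype
  displaced by an isotropic Gaussian with standard deviation σ, plus an
  independent offspring-type background. µ controls attraction strength,
  σ its spatial scale; µ = 0 recovers CSR.
* **Repulsion** (Matérn-II cross-type hard core): CSR for two phenotypes
  followed by dependent thinning — in any cross-type pair closer than the
  hard-core radius, the later-born point is deleted, so no surviving
  cross-type pair is closer than the hard-core distance and cross-type EP at
  any radius below it is exactly 0.

Windows are rectangles in µm (default 1000 × 1000). On a torus boundary,
offspring displacements wrap; without it, offspring falling outside the
window are discarded (border thinning — a small intensity bias near edges;
the torus is the preferred mode when comparing to closed forms). Everything
is deterministic under the config seed, including cohorts: per-sample seeds
are spawned from the master seed by sample index, so generation order is
irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .celltable import CellTable, SampleMeta
from .errors import ValidationError

import logging

logger = logging.getLogger(__name__)


@dataclass
class AttractionSpec:
    """Thomas-cluster attraction between a parent and an offspring phenotype.

    ``parent_intensity`` λ_c is the parent Poisson intensity (cells/µm²);
    each parent spawns Poisson(``mean_offspring`` µ) offspring displaced by
    Gaussian(``dispersion`` σ, in µm); ``offspring_background`` λ_bg adds an
    independent CSR component of the offspring phenotype.
    """

    parent_phenotype: str
    offspring_phenotype: str
    parent_intensity: float
    mean_offspring: float = 4.0
    dispersion: float = 5.0
    offspring_background: float = 0.0

    def __post_init__(self) -> None:
        if min(self.parent_intensity, self.mean_offspring,
               self.offspring_background) < 0:
            raise ValidationError("attraction intensities must be >= 0")
        if not self.dispersion > 0:
            raise ValidationError("dispersion must be > 0")


@dataclass
class TissueSimConfig:
    """Window, intensities and interaction structure for one simulated sample."""

    seed: int
    window: tuple = (1000.0, 1000.0)
    boundary: str = "torus"
    background_intensities: dict = field(default_factory=dict)
    attraction: Optional[AttractionSpec] = None
    hardcore_radius: Optional[float] = None
    hardcore_phenotypes: Optional[tuple] = None
    sample_id: str = "sim"
    group: str = ""

    def __post_init__(self) -> None:
        w, h = self.window
        if not (w > 0 and h > 0):
            raise ValidationError("window dimensions must be > 0")
        if self.boundary not in ("none", "torus"):
            raise ValidationError(f"unknown boundary: {self.boundary}")
        if any(lam < 0 for lam in self.background_intensities.values()):
            raise ValidationError("intensities must be >= 0")

    @property
    def area(self) -> float:
        return float(self.window[0]) * float(self.window[1])


def _poisson_points(rng: np.random.Generator, intensity: float,
                    window) -> np.ndarray:
    n = rng.poisson(intensity * window[0] * window[1])
    pts = np.empty((n, 2))
    pts[:, 0] = rng.uniform(0, window[0], n)
    pts[:, 1] = rng.uniform(0, window[1], n)
    return pts


def _to_table(config: TissueSimConfig, points, labels, ground_truth=None) -> CellTable:
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    cells = pd.DataFrame({
        "x": points[:, 0], "y": points[:, 1],
        "phenotype": labels, "region": "other",
    })
    meta = SampleMeta(sample_id=config.sample_id, group=config.group)
    return CellTable(meta=meta, cells=cells, ground_truth=ground_truth or {})


def simulate_csr(config: TissueSimConfig) -> CellTable:
    """Independent homogeneous Poisson pattern per phenotype (the CSR null)."""
    if config.attraction is not None:
        raise ValidationError("simulate_csr requires attraction=None")
    rng = np.random.default_rng(config.seed)
    pts, labels = [], []
    for phen in sorted(config.background_intensities):
        p = _poisson_points(rng, config.background_intensities[phen], config.window)
        pts.append(p)
        labels.extend([phen] * len(p))
    all_pts = np.vstack(pts) if pts else np.empty((0, 2))
    if len(all_pts) == 0:
        logger.warning("simulate_csr(%s): empty table (zero total intensity)",
                       config.sample_id)
    return _to_table(config, all_pts, labels,
                     {"model": "csr",
                      "intensities": dict(config.background_intensities)})


def simulate_attraction(config: TissueSimConfig) -> CellTable:
    """Thomas-cluster attraction between the configured parent/offspring pair,
    on top of any CSR background phenotypes."""
    spec = config.attraction
    if spec is None:
        raise ValidationError("simulate_attraction requires an AttractionSpec")
    rng = np.random.default_rng(config.seed)
    window = np.asarray(config.window, dtype=float)

    pts, labels = [], []
    for phen in sorted(config.background_intensities):
        p = _poisson_points(rng, config.background_intensities[phen], config.window)
        pts.append(p)
        labels.extend([phen] * len(p))

    parents = _poisson_points(rng, spec.parent_intensity, config.window)
    pts.append(parents)
    labels.extend([spec.parent_phenotype] * len(parents))

    n_offspring = rng.poisson(spec.mean_offspring, size=len(parents))
    total = int(n_offspring.sum())
    if total:
        centers = np.repeat(parents, n_offspring, axis=0)
        offspring = centers + rng.normal(0.0, spec.dispersion, size=(total, 2))
        if config.boundary == "torus":
            offspring = np.mod(offspring, window)
        else:
            inside = ((offspring >= 0) & (offspring < window)).all(axis=1)
            offspring = offspring[inside]
        pts.append(offspring)
        labels.extend([spec.offspring_phenotype] * len(offspring))

    bg = _poisson_points(rng, spec.offspring_background, config.window)
    pts.append(bg)
    labels.extend([spec.offspring_phenotype] * len(bg))

    return _to_table(config, np.vstack(pts) if pts else np.empty((0, 2)), labels,
                     {"model": "thomas", "mu": spec.mean_offspring,
                      "sigma": spec.dispersion,
                      "parent_intensity": spec.parent_intensity,
                      "offspring_background": spec.offspring_background})


def _torus_dist2(a: np.ndarray, b: np.ndarray, window) -> np.ndarray:
    d = np.abs(a[:, None, :] - b[None, :, :])
    d = np.minimum(d, np.asarray(window) - d)
    return (d ** 2).sum(axis=2)


def simulate_hardcore(config: TissueSimConfig) -> CellTable:
    """Cross-type Matérn-II thinning: CSR per phenotype, then in every pair of
    cells of the two hard-core phenotypes closer than ``hardcore_radius`` the
    later-born cell is deleted (birth times uniform). No surviving cross-type
    pair is closer than the hard-core distance."""
    if config.hardcore_radius is None:
        raise ValidationError("simulate_hardcore requires hardcore_radius")
    rng = np.random.default_rng(config.seed)
    phens = sorted(config.background_intensities)
    pair = config.hardcore_phenotypes
    if pair is None:
        if len(phens) != 2:
            raise ValidationError(
                "hardcore_phenotypes required unless exactly two phenotypes")
        pair = (phens[0], phens[1])

    pts, labels = [], []
    for phen in phens:
        p = _poisson_points(rng, config.background_intensities[phen], config.window)
        pts.append(p)
        labels.extend([phen] * len(p))
    points = np.vstack(pts) if pts else np.empty((0, 2))
    labels = np.asarray(labels, dtype=object)

    r = config.hardcore_radius
    keep = np.ones(len(points), dtype=bool)
    if r > 0 and len(points):
        a_idx = np.flatnonzero(labels == pair[0])
        b_idx = np.flatnonzero(labels == pair[1])
        if len(a_idx) and len(b_idx):
            birth = rng.uniform(size=len(points))
            if config.boundary == "torus":
                d2 = _torus_dist2(points[a_idx], points[b_idx], config.window)
            else:
                diff = points[a_idx, None, :] - points[None, b_idx, :]
                d2 = (diff ** 2).sum(axis=2)
            close = d2 < r * r
            for i, j in zip(*np.nonzero(close)):
                # delete the later-born member of each close cross-type pair,
                # judged on the primary (unthinned) pattern
                if birth[a_idx[i]] < birth[b_idx[j]]:
                    keep[b_idx[j]] = False
                else:
                    keep[a_idx[i]] = False
    return _to_table(config, points[keep], list(labels[keep]),
                     {"model": "hardcore", "hardcore_radius": r,
                      "pair": tuple(pair)})


def simulate(config: TissueSimConfig) -> CellTable:
    """Dispatch on the configured structure (attraction > hardcore > CSR)."""
    if config.attraction is not None:
        return simulate_attraction(config)
    if config.hardcore_radius is not None:
        return simulate_hardcore(config)
    return simulate_csr(config)


@dataclass
class CohortSimConfig:
    """Two-arm cohort: ``n_pos`` samples from ``config_pos`` and ``n_neg``
    from ``config_neg``, which should differ only in attraction parameters.
    Per-sample seeds are spawned deterministically from ``seed``."""

    n_pos: int
    n_neg: int
    config_pos: TissueSimConfig
    config_neg: TissueSimConfig
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValidationError("need >= 1 sample per arm")


def _sample_seed(master: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def simulate_cohort(config: CohortSimConfig):
    """Generate the cohort.

    Returns ``(tables, manifest)``: the list of :class:`CellTable` (positive
    arm first) with group labels on their metadata, and a manifest DataFrame
    recording per-sample ids, groups, seeds and the ground-truth attraction
    parameters of each arm.
    """
    tables, rows = [], []
    specs = [("pos", config.config_pos, config.n_pos),
             ("neg", config.config_neg, config.n_neg)]
    index = 0
    for arm, base, n in specs:
        group = base.group or arm
        for k in range(n):
            seed = _sample_seed(config.seed, index)
            cfg = replace(base, seed=seed,
                          sample_id=f"{group}_{k:03d}", group=group)
            table = simulate(cfg)
            tables.append(table)
            row = {"sample_id": cfg.sample_id, "group": group, "seed": seed}
            row.update({k: v for k, v in table.ground_truth.items()
                        if not isinstance(v, dict)})
            rows.append(row)
            index += 1
    return tables, pd.DataFrame(rows)
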
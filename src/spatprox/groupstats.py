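"""Group comparisons and single-sample spatial association tests.

Two inferential layers sit on top of the proximity metrics:

* **Between-group contrasts** — per-sample metric values (ES, EP, density,
  ratio) compared between cohort arms with the Mann–Whitney U rank-sum test.
  For small samples (n_a + n_b <= 12) the full permutation distribution of
  the midrank U statistic is enumerated, which is exact with or without
  ties; larger samples use the tie- and continuity-corrected normal
  approximation. Missing metric values (undefined ES/EP) are excluded and
  the exclusion count is reported, so an absent phenotype never masquerades
  as zero proximity.
* **Within-sample association** — a label-permutation test of spatial
  association for a single cell table: phenotype labels are shuffled over
  the fixed coordinates, which preserves the overall geometry while breaking
  any label-coordinate dependence. The default alternative is attraction
  (observed ES greater than under the shuffled null); the p-value uses the
  add-one estimator p = (1 + #{ES_perm >= ES_obs}) / (1 + n_perm), which is
  valid (never anti-conservative) and never exactly zero.

Multiplicity over phenotype pairs is controlled with Benjamini–Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from scipy.sparse import csr_matrix
from statsmodels.stats.multitest import multipletests

from .celltable import CellTable
from .errors import UndefinedTestError, ValidationError
from .proximity import ProximityQuery, proximity
from .errors import UndefinedMetricError

EXACT_MAX_N = 12


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    p_value: float
    method: str                     # "exact" | "approximate" | "permutation"
    n: tuple = ()
    adjusted_p: Optional[float] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value outside [0,1]: {self.p_value}")


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[np.isfinite(arr)]


def _exact_mw_p(a: np.ndarray, b: np.ndarray, alternative: str) -> tuple:
    """Enumerate the permutation distribution of the midrank U statistic.

    Exact under ties; feasible because C(12, 6) = 924 assignments at most.
    The distribution of U_a is symmetric about n_a*n_b/2 (U_a + U_b is
    constant and the arms are exchangeable under the null).
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a, n = len(a), len(pooled)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    u_all = np.array([
        ranks[list(idx)].sum() - n_a * (n_a + 1) / 2
        for idx in combinations(range(n), n_a)
    ])
    total = len(u_all)
    center = n_a * (n - n_a) / 2
    eps = 1e-9
    if alternative == "two-sided":
        p = (np.abs(u_all - center) >= abs(u_obs - center) - eps).sum() / total
    elif alternative == "greater":
        p = (u_all >= u_obs - eps).sum() / total
    elif alternative == "less":
        p = (u_all <= u_obs + eps).sum() / total
    else:
        raise ValidationError(f"unknown alternative: {alternative}")
    return float(u_obs), min(1.0, float(p))


def mann_whitney_u(values_a, values_b, alternative: str = "two-sided") -> TestResult:
    """Mann–Whitney U rank-sum test between two value sets.

    Non-finite values are dropped (count recorded in ``extra['n_excluded']``).
    With n_a + n_b <= 12 the exact permutation distribution is enumerated
    (method tag ``exact``); otherwise the normal approximation with tie and
    continuity correction is used (``approximate``).
    """
    a, b = _clean(values_a), _clean(values_b)
    n_excluded = (len(np.atleast_1d(values_a)) - len(a)) + \
                 (len(np.atleast_1d(values_b)) - len(b))
    if len(a) == 0 or len(b) == 0:
        raise UndefinedTestError("a group has no non-missing values")
    if len(a) + len(b) <= EXACT_MAX_N:
        u, p = _exact_mw_p(a, b, alternative)
        method = "exact"
    else:
        u, p = stats.mannwhitneyu(a, b, alternative=alternative,
                                  method="asymptotic", use_continuity=True)
        method = "approximate"
    return TestResult(statistic=float(u), p_value=float(p), method=method,
                      n=(len(a), len(b)), extra={"n_excluded": int(n_excluded)})


def wilcoxon_signed_rank(values_a, values_b, alternative: str = "two-sided") -> TestResult:
    """Paired-sample companion to :func:`mann_whitney_u` (Wilcoxon signed-rank),
    for matched designs such as pre/post treatment pairs."""
    a, b = np.asarray(values_a, float), np.asarray(values_b, float)
    if a.shape != b.shape:
        raise ValidationError("paired samples must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 1:
        raise UndefinedTestError("no complete pairs")
    res = stats.wilcoxon(a[ok], b[ok], alternative=alternative)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="approximate", n=(int(ok.sum()),))


# ---------------------------------------------------------------------------
# Label-permutation spatial association
# ---------------------------------------------------------------------------

def _adjacency(table: CellTable, radius: float, boundary: str, window):
    """Symmetric sparse cell-cell adjacency at the query radius (no self loops)."""
    coords = table.coords
    boxsize = None
    if boundary == "torus":
        boxsize = np.asarray(window, dtype=float)
        coords = np.mod(coords, boxsize)
    tree = cKDTree(coords, boxsize=boxsize)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    n = len(coords)
    if len(pairs) == 0:
        return csr_matrix((n, n), dtype=np.int8)
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    return csr_matrix((np.ones(len(rows), np.int8), (rows, cols)), shape=(n, n))


def _es_from_adjacency(adj, central_mask, surrounding_mask, mode: str) -> float:
    n_c = int(central_mask.sum())
    if mode == "sum_neighbors":
        return float(central_mask @ (adj @ surrounding_mask)) / n_c
    near_central = (adj @ central_mask) > 0
    return float((near_central & (surrounding_mask > 0)).sum()) / n_c


def permutation_association(table: CellTable, query: ProximityQuery,
                            n_perm: int = 999, seed: int = 0,
                            alternative: str = "greater") -> TestResult:
    """Test spatial association between two phenotypes in one sample by
    shuffling all phenotype labels over the fixed coordinates.

    ``alternative="greater"`` tests for attraction (ES above the shuffled
    null); ``"two-sided"`` uses the absolute deviation from the null mean.
    Deterministic under ``seed``. With ``n_perm=0`` the add-one estimator
    gives p = 1.
    """
    labels = table.cells["phenotype"].to_numpy()
    central_mask = (labels == query.central).astype(np.float64)
    surrounding_mask = (labels == query.surrounding).astype(np.float64)
    if central_mask.sum() == 0 or surrounding_mask.sum() == 0:
        raise UndefinedTestError("both phenotypes must be present")
    adj = _adjacency(table, query.radius, query.boundary, query.window)
    es_obs = _es_from_adjacency(adj, central_mask, surrounding_mask,
                                query.counting_mode)
    rng = np.random.default_rng(seed)
    es_perm = np.empty(n_perm)
    idx = np.arange(len(labels))
    for k in range(n_perm):
        rng.shuffle(idx)
        es_perm[k] = _es_from_adjacency(adj, central_mask[idx],
                                        surrounding_mask[idx],
                                        query.counting_mode)
    if alternative == "greater":
        extreme = int((es_perm >= es_obs - 1e-12).sum())
    elif alternative == "less":
        extreme = int((es_perm <= es_obs + 1e-12).sum())
    elif alternative == "two-sided":
        null_mean = es_perm.mean() if n_perm else 0.0
        extreme = int((np.abs(es_perm - null_mean)
                       >= abs(es_obs - null_mean) - 1e-12).sum())
    else:
        raise ValidationError(f"unknown alternative: {alternative}")
    p = (1 + extreme) / (1 + n_perm)
    return TestResult(statistic=es_obs, p_value=float(p), method="permutation",
                      n=(int(central_mask.sum()), int(surrounding_mask.sum())),
                      extra={"n_perm": n_perm, "null_mean":
                             float(es_perm.mean()) if n_perm else float("nan")})


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving,
    monotone, elementwise >= raw)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def correlate_infiltrates(values_x, values_y, method: str = "spearman"):
    """Correlate two per-sample infiltrate measures (e.g. macrophage vs
    cytotoxic-T-cell abundance) across samples.

    Pairs with any missing value are dropped; needs >= 3 complete pairs and
    non-constant inputs. Returns ``(coefficient, TestResult)``.
    """
    x = np.asarray(values_x, dtype=float)
    y = np.asarray(values_y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise UndefinedTestError("need >= 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedTestError("constant input: correlation undefined")
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    elif method == "pearson":
        rho, p = stats.pearsonr(x, y)
    else:
        raise ValidationError(f"unknown method: {method}")
    return float(rho), TestResult(statistic=float(rho), p_value=float(p),
                                  method="approximate", n=(len(x),))


# ---------------------------------------------------------------------------
# Cohort-level proximity screen
# ---------------------------------------------------------------------------

def cohort_metric_table(tables, phenotypes, radius: float = 20.0,
                        counting_mode: str = "sum_neighbors",
                        boundary: str = "none", window=None) -> pd.DataFrame:
    """Per-sample ES and EP for every ordered phenotype pair across a cohort.

    Undefined metrics (absent central phenotype) appear as NaN. Columns:
    sample_id, group, central, surrounding, es, ep.
    """
    rows = []
    for table in tables:
        for central in phenotypes:
            for surrounding in phenotypes:
                if central == surrounding:
                    continue
                q = ProximityQuery(central=central, surrounding=surrounding,
                                   radius=radius, counting_mode=counting_mode,
                                   boundary=boundary, window=window)
                try:
                    res = proximity(table, q)
                    es, ep = res.es, res.ep
                except UndefinedMetricError:
                    es = ep = float("nan")
                rows.append({"sample_id": table.meta.sample_id,
                             "group": table.meta.group,
                             "central": central, "surrounding": surrounding,
                             "es": es, "ep": ep})
    return pd.DataFrame(rows)


def proximity_contrast(metric_table: pd.DataFrame, group_a: str, group_b: str,
                       metric: str = "es") -> pd.DataFrame:
    """Screen every ordered phenotype pair for a between-group difference in
    a proximity metric: Mann–Whitney per pair, BH adjustment across pairs.

    Returns one row per (central, surrounding) pair with the U statistic,
    raw and BH-adjusted p-values, and per-group sample counts.
    """
    rows = []
    for (central, surrounding), sub in metric_table.groupby(
            ["central", "surrounding"], sort=True):
        va = sub.loc[sub["group"] == group_a, metric]
        vb = sub.loc[sub["group"] == group_b, metric]
        try:
            res = mann_whitney_u(va, vb)
            rows.append({"central": central, "surrounding": surrounding,
                         "statistic": res.statistic, "p_value": res.p_value,
                         "n_a": res.n[0], "n_b": res.n[1]})
        except UndefinedTestError:
            rows.append({"central": central, "surrounding": surrounding,
                         "statistic": float("nan"), "p_value": float("nan"),
                         "n_a": 0, "n_b": 0})
    out = pd.DataFrame(rows)
    ok = out["p_value"].notna()
    out["adjusted_p"] = float("nan")
    if ok.any():
        out.loc[ok, "adjusted_p"] = bh_adjust(out.loc[ok, "p_value"].to_numpy())
    return out
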
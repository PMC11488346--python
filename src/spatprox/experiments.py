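"""Simulation studies that validate the proximity statistics end to end.

Each study generates synthetic tissue under known conditions, runs the full
metric + test pipeline, and summarizes how the estimates relate to their
analytic or configured ground truth:

* :func:`csr_closed_form_study` — under complete spatial randomness on a
  torus, mean ES must approach λ·π·r² and mean EP must approach
  1 − exp(−λ·π·r²) (the Poisson void probability).
* :func:`cohort_power_study` — two 15-sample arms differing only in the
  Thomas attraction strength (µ = 6 vs µ = 0 at σ = 5 µm); the fraction of
  cohort replicates in which the Mann–Whitney ES contrast reaches p < .05
  estimates the detection power.
* :func:`null_calibration_study` — on CSR tables the label-permutation
  association test must reject at close to its nominal level.

All studies are deterministic given their seed; per-replicate seeds are
spawned from it.
"""

from __future__ import annotations

import numpy as np

from .groupstats import mann_whitney_u, permutation_association
from .proximity import ProximityQuery, proximity
from .tissue import (AttractionSpec, CohortSimConfig, TissueSimConfig,
                     _sample_seed, simulate_cohort, simulate_csr)


def csr_closed_form_study(n_replicates: int = 200, lam_surround: float = 1e-3,
                          lam_central: float = 3e-4, radius: float = 20.0,
                          window=(1000.0, 1000.0), seed: int = 0) -> dict:
    """Mean ES/EP over CSR replicates vs their closed-form expectations."""
    es_vals, ep_vals = [], []
    q = ProximityQuery("central", "surrounding", radius,
                       boundary="torus", window=window)
    for k in range(n_replicates):
        cfg = TissueSimConfig(
            seed=_sample_seed(seed, k), window=window, boundary="torus",
            background_intensities={"central": lam_central,
                                    "surrounding": lam_surround})
        res = proximity(simulate_csr(cfg), q)
        es_vals.append(res.es)
        ep_vals.append(res.ep)
    es_vals, ep_vals = np.asarray(es_vals), np.asarray(ep_vals)
    mu = lam_surround * np.pi * radius ** 2
    return {
        "mean_es": float(es_vals.mean()),
        "se_es": float(es_vals.std(ddof=1) / np.sqrt(n_replicates)),
        "expected_es": float(mu),
        "mean_ep": float(ep_vals.mean()),
        "se_ep": float(ep_vals.std(ddof=1) / np.sqrt(n_replicates)),
        "expected_ep": float(1 - np.exp(-mu)),
        "n_replicates": n_replicates,
    }


def _attraction_arm(mu: float, sigma: float = 5.0,
                    window=(1000.0, 1000.0)) -> TissueSimConfig:
    spec = AttractionSpec("parent", "offspring", parent_intensity=2e-4,
                          mean_offspring=mu, dispersion=sigma,
                          offspring_background=1e-4)
    return TissueSimConfig(seed=0, window=window, boundary="torus",
                           attraction=spec)


def cohort_power_study(n_replicates: int = 25, n_per_arm: int = 15,
                       mu_pos: float = 6.0, mu_neg: float = 0.0,
                       sigma: float = 5.0, radius: float = 20.0,
                       window=(1000.0, 1000.0), alpha: float = 0.05,
                       seed: int = 0) -> dict:
    """Fraction of simulated cohorts in which the between-arm ES contrast is
    detected by the Mann–Whitney test at the given level."""
    q = ProximityQuery("parent", "offspring", radius,
                       boundary="torus", window=window)
    p_values = []
    for k in range(n_replicates):
        cohort = CohortSimConfig(
            n_pos=n_per_arm, n_neg=n_per_arm, seed=_sample_seed(seed, k),
            config_pos=_attraction_arm(mu_pos, sigma, window),
            config_neg=_attraction_arm(mu_neg, sigma, window))
        tables, manifest = simulate_cohort(cohort)
        es = np.array([proximity(t, q).es for t in tables])
        pos = manifest["group"].to_numpy() == "pos"
        p_values.append(mann_whitney_u(es[pos], es[~pos]).p_value)
    p_values = np.asarray(p_values)
    return {
        "power": float((p_values < alpha).mean()),
        "p_values": p_values,
        "n_replicates": n_replicates,
        "alpha": alpha,
    }


def null_calibration_study(n_tables: int = 200, n_perm: int = 199,
                           lam: float = 1e-3, radius: float = 20.0,
                           window=(500.0, 500.0), alpha: float = 0.05,
                           seed: int = 0) -> dict:
    """Rejection rate of the label-permutation association test on CSR
    tables, which should sit at the nominal level."""
    q = ProximityQuery("A", "B", radius, boundary="torus", window=window)
    rejections = 0
    for k in range(n_tables):
        table_seed = _sample_seed(seed, k)
        cfg = TissueSimConfig(seed=table_seed, window=window, boundary="torus",
                              background_intensities={"A": lam, "B": lam})
        res = permutation_association(simulate_csr(cfg), q, n_perm=n_perm,
                                      seed=table_seed + 1)
        if res.p_value <= alpha:
            rejections += 1
    rate = rejections / n_tables
    return {
        "rejection_rate": rate,
        "se": float(np.sqrt(alpha * (1 - alpha) / n_tables)),
        "n_tables": n_tables,
        "alpha": alpha,
        "n_perm": n_perm,
    }
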
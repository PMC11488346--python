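import numpy as np
import pandas as pd
import pytest

from spatprox import CellTable, SampleMeta


def make_table(points_by_phenotype, sample_id="t", group="", region=None):
    """Build a CellTable from {phenotype: [(x, y), ...]}."""
    rows = []
    for phen, pts in points_by_phenotype.items():
        for x, y in pts:
            rows.append({"x": float(x), "y": float(y), "phenotype": phen,
                         "region": region or "other"})
    cells = pd.DataFrame(rows, columns=["x", "y", "phenotype", "region"])
    return CellTable(meta=SampleMeta(sample_id=sample_id, group=group),
                     cells=cells)


def random_table(rng, n_cells, phenotypes=("A", "B"), window=(400.0, 400.0)):
    """Uniform random table with labels drawn uniformly over the phenotypes."""
    cells = pd.DataFrame({
        "x": rng.uniform(0, window[0], n_cells),
        "y": rng.uniform(0, window[1], n_cells),
        "phenotype": rng.choice(list(phenotypes), n_cells),
    })
    return CellTable(meta=SampleMeta(sample_id="rand"), cells=cells)


def brute_force_counts(table, central, surrounding, radius,
                       boundary="none", window=None):
    """All-pairs distance scan: the oracle for count_neighbors."""
    cells = table.cells
    c = cells.loc[cells["phenotype"] == central, ["x", "y"]].to_numpy(float)
    s = cells.loc[cells["phenotype"] == surrounding, ["x", "y"]].to_numpy(float)
    same = central == surrounding
    counts = np.zeros(len(c), dtype=int)
    for i, p in enumerate(c):
        for j, q in enumerate(s):
            if same and i == j:
                continue
            d = np.abs(p - q)
            if boundary == "torus":
                d = np.minimum(d, np.asarray(window) - d)
            if float(np.hypot(d[0], d[1])) <= radius:
                counts[i] += 1
    return counts


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
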
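"""Phenotype-labelled cell centroid tables.

The unit of analysis is one multiplex-immunofluorescence sample: a table of
segmented cell centroids, each carrying a hard phenotype call (one label per
cell, e.g. ``panCK+`` or ``FAP+``) and a pathologist region annotation from
the vocabulary ``{TC, IM, other}`` (tumour core / invasive margin / anything
else). Coordinates are continuous centroids in micrometres with an arbitrary
origin; tables exported in pixel units are rescaled on load via the
``pixel_to_um`` factor on :class:`SampleMeta`. All downstream geometry is
centroid-to-centroid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Allowed region annotations. Finer structures (lymphoid follicles,
#: muscularis, ...) are collapsed to "other".
REGION_VOCABULARY = frozenset({"TC", "IM", "other"})

#: Canonical column order for normalized CSV output.
COLUMNS = ["cell_id", "x", "y", "phenotype", "region"]


@dataclass
class SampleMeta:
    """Per-sample metadata.

    Parameters
    ----------
    sample_id : str
        Opaque sample identifier.
    group : str
        Cohort arm label (e.g. ``GCPM_pos`` / ``GCPM_neg``); free-form.
    tissue : str
        Tissue of origin (e.g. ``PT`` primary tumour, ``PM`` peritoneal
        metastasis); free-form.
    pixel_to_um : float
        Micrometres per raw coordinate unit; 1.0 means coordinates are
        already in µm. Must be positive.
    """

    sample_id: str
    group: str = ""
    tissue: str = ""
    pixel_to_um: float = 1.0

    def __post_init__(self) -> None:
        if not self.pixel_to_um > 0:
            raise ValidationError(f"pixel_to_um must be > 0, got {self.pixel_to_um}")


@dataclass
class CellTable:
    """One sample's cell centroids with phenotype and region labels.

    ``cells`` is a DataFrame with columns ``cell_id, x, y, phenotype, region``;
    coordinates are in µm (already scaled), ``cell_id`` is unique within the
    table, and ``region`` is drawn from :data:`REGION_VOCABULARY`.
    """

    meta: SampleMeta
    cells: pd.DataFrame
    n_dropped: int = 0
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cells = _normalize(self.cells)

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) float array of centroid coordinates in µm."""
        return self.cells[["x", "y"]].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "CellTable":
        return CellTable(meta=replace(self.meta), cells=self.cells.loc[mask].copy(),
                         ground_truth=dict(self.ground_truth))


def _normalize(cells: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a cell DataFrame (column order, invariants)."""
    for col in ("x", "y", "phenotype"):
        if col not in cells.columns:
            raise FormatError(f"missing mandatory column: {col!r}")
    cells = cells.copy()
    if "cell_id" not in cells.columns:
        cells["cell_id"] = [f"c{i}" for i in range(len(cells))]
    if "region" not in cells.columns:
        cells["region"] = "other"
    cells["region"] = cells["region"].fillna("other")
    bad_regions = set(cells["region"]) - REGION_VOCABULARY
    if bad_regions:
        raise ValidationError(f"region labels outside vocabulary: {sorted(bad_regions)}")
    if cells["cell_id"].duplicated().any():
        dupes = cells.loc[cells["cell_id"].duplicated(), "cell_id"].unique()[:5]
        raise ValidationError(f"duplicate cell_id values: {list(dupes)}")
    coords = cells[["x", "y"]].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        raise ValidationError("non-finite coordinates in cell table")
    if (cells["phenotype"].astype(str) == "").any():
        raise ValidationError("empty phenotype label")
    return cells[COLUMNS].reset_index(drop=True)


def read_cell_table(path, meta: SampleMeta) -> CellTable:
    """Load a cell table from CSV, clean it, and scale coordinates to µm.

    Expects a header row with at least ``x``, ``y`` and ``phenotype`` columns
    (``cell_id`` and ``region`` optional, as in inForm-style segmentation
    exports). Rows with missing or non-numeric coordinates are dropped and
    counted; the drop count is logged and stored on the returned table as
    ``n_dropped``. Coordinates are multiplied by ``meta.pixel_to_um``.

    Raises
    ------
    FormatError
        If a mandatory column is absent.
    EmptyInputError
        If no rows survive cleaning.
    """
    raw = pd.read_csv(path)
    for col in ("x", "y", "phenotype"):
        if col not in raw.columns:
            raise FormatError(f"missing mandatory column: {col!r} in {path}")
    raw["x"] = pd.to_numeric(raw["x"], errors="coerce")
    raw["y"] = pd.to_numeric(raw["y"], errors="coerce")
    keep = np.isfinite(raw["x"].to_numpy()) & np.isfinite(raw["y"].to_numpy())
    n_dropped = int((~keep).sum())
    cleaned = raw.loc[keep].copy()
    if cleaned.empty:
        raise EmptyInputError(f"no cells with finite coordinates in {path}")
    cleaned["x"] = cleaned["x"] * meta.pixel_to_um
    cleaned["y"] = cleaned["y"] * meta.pixel_to_um
    if n_dropped:
        logger.info("read_cell_table(%s): dropped %d row(s) with bad coordinates",
                    meta.sample_id, n_dropped)
    return CellTable(meta=meta, cells=cleaned, n_dropped=n_dropped)


def write_cell_table(table: CellTable, path) -> None:
    """Write a cell table as normalized CSV (canonical columns, µm coordinates)."""
    table.cells[COLUMNS].to_csv(path, index=False)


def filter_by_region(table: CellTable, regions) -> CellTable:
    """Restrict a table to cells in the given region labels; metadata unchanged.

    An empty result is allowed (logged) — e.g. asking for IM cells in an
    all-TC sample.
    """
    regions = set(regions)
    if not regions:
        raise ValidationError("regions must be non-empty")
    bad = regions - REGION_VOCABULARY
    if bad:
        raise ValidationError(f"unknown region label(s): {sorted(bad)}")
    out = table.subset(table.cells["region"].isin(regions).to_numpy())
    if len(out) == 0:
        logger.warning("filter_by_region(%s, %s): empty result",
                       table.meta.sample_id, sorted(regions))
    return out


def phenotype_counts(table: CellTable) -> dict:
    """Count cells per phenotype; phenotypes absent from the table are absent
    from the mapping, and counts sum to ``len(table)``."""
    return table.cells["phenotype"].value_counts().to_dict()
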
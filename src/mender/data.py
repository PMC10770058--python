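"""Multi-slice spatial dataset container, validation and file I/O.

A :class:`SpatialDataset` bundles everything a multi-slice spatial omics
experiment provides: a cells x genes expression matrix, per-cell spatial
coordinates (2-D or 3-D, in micrometers unless ``unit_scale`` says
otherwise), a per-cell slice identifier, and optional per-cell labels
(cell state, predicted domain, ground-truth domain) plus arbitrary
metadata.  Cells from different slices never share a coordinate frame;
the ``slice_id`` column is what keeps them spatially insulated
downstream.

On disk, datasets live either in an AnnData/h5ad container (expression
in ``X``, labels in ``obs``, coordinates under ``obsm["spatial"]``) or
as plain tables (``expression.mtx``/``expression.csv`` + ``cells.csv`` +
``genes.csv``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import scipy.sparse as sp

SLICE_KEY = "slice_id"
SPATIAL_KEY = "spatial"

_LABEL_COLUMNS = ("cell_state", "domain", "truth_domain")


class MissingSliceKeyError(KeyError):
    """Raised when the multi-slice key ``slice_id`` is absent from an input."""


class ShapeMismatchError(ValueError):
    """Raised when per-cell arrays disagree on the number of cells."""


@dataclass
class ValidationIssue:
    severity: Literal["error", "warning"]
    message: str
    indices: list[int] = field(default_factory=list)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate`: ``ok`` iff no error-severity issue."""

    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]


@dataclass
class SpatialDataset:
    """In-memory multi-slice spatial omics dataset.

    Parameters
    ----------
    expression
        N x G matrix of nonnegative expression values (dense ndarray or
        scipy sparse).  Raw counts are assumed but not enforced; the
        pipeline normalizes internally.
    coordinates
        N x D spatial coordinates, D in {2, 3}.  Stored in the file's
        native units; ``unit_scale`` converts them to micrometers before
        any radius-based logic.
    slice_id
        Length-N identifier of the tissue section each cell comes from.
    """

    expression: np.ndarray | sp.spmatrix
    coordinates: np.ndarray
    slice_id: np.ndarray
    var_names: np.ndarray | None = None
    cell_state: np.ndarray | None = None
    domain: np.ndarray | None = None
    truth_domain: np.ndarray | None = None
    obs: pd.DataFrame | None = None
    unit_scale: float = 1.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] not in (2, 3):
            raise ValueError(
                f"coordinates must be N x 2 or N x 3, got shape {self.coordinates.shape}"
            )
        if not sp.issparse(self.expression):
            self.expression = np.asarray(self.expression)
        self.slice_id = np.asarray(self.slice_id)
        n = self.expression.shape[0]
        for name, arr in [
            ("coordinates", self.coordinates),
            ("slice_id", self.slice_id),
            ("cell_state", self.cell_state),
            ("domain", self.domain),
            ("truth_domain", self.truth_domain),
        ]:
            if arr is not None and len(arr) != n:
                raise ShapeMismatchError(
                    f"expression has {n} rows but {name} has {len(arr)}"
                )
        if self.obs is not None and len(self.obs) != n:
            raise ShapeMismatchError(
                f"expression has {n} rows but obs table has {len(self.obs)}"
            )
        if self.var_names is None:
            self.var_names = np.array([f"g{i}" for i in range(self.expression.shape[1])])
        else:
            self.var_names = np.asarray(self.var_names, dtype=object)
            if len(self.var_names) != self.expression.shape[1]:
                raise ShapeMismatchError(
                    f"expression has {self.expression.shape[1]} columns but "
                    f"var_names has {len(self.var_names)}"
                )

    # -- basic properties ------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    @property
    def slices(self) -> np.ndarray:
        """Slice identifiers in order of first appearance."""
        return pd.unique(self.slice_id)

    def coords_um(self) -> np.ndarray:
        """Coordinates converted to micrometers via ``unit_scale``."""
        return self.coordinates * float(self.unit_scale)

    def slice_mask(self, slice_value) -> np.ndarray:
        mask = self.slice_id == slice_value
        if not mask.any():
            raise KeyError(f"unknown slice {slice_value!r}")
        return mask

    # -- conversion ------------------------------------------------------
    def to_anndata(self):
        import anndata as ad

        obs = pd.DataFrame(index=[f"cell{i}" for i in range(self.n_cells)])
        obs[SLICE_KEY] = pd.Categorical(self.slice_id.astype(str))
        for col in _LABEL_COLUMNS:
            val = getattr(self, col)
            if val is not None:
                obs[col] = pd.Categorical(np.asarray(val).astype(str))
        if self.obs is not None:
            for col in self.obs.columns:
                obs[col] = np.asarray(self.obs[col])
        X = self.expression
        adata = ad.AnnData(
            X=X if sp.issparse(X) else np.asarray(X),
            obs=obs,
            var=pd.DataFrame(index=self.var_names.astype(str)),
        )
        adata.obsm[SPATIAL_KEY] = self.coordinates
        adata.uns["unit_scale"] = float(self.unit_scale)
        return adata

    @classmethod
    def from_anndata(cls, adata) -> "SpatialDataset":
        if SLICE_KEY not in adata.obs:
            raise MissingSliceKeyError(
                f"multi-slice key absent: obs column {SLICE_KEY!r} is required"
            )
        if SPATIAL_KEY not in adata.obsm:
            raise KeyError(f"obsm key {SPATIAL_KEY!r} (coordinates) is required")
        kwargs = {}
        for col in _LABEL_COLUMNS:
            if col in adata.obs:
                kwargs[col] = np.asarray(adata.obs[col].astype(str))
        extra = [
            c for c in adata.obs.columns if c != SLICE_KEY and c not in _LABEL_COLUMNS
        ]
        obs = adata.obs[extra].reset_index(drop=True) if extra else None
        return cls(
            expression=adata.X.copy() if sp.issparse(adata.X) else np.asarray(adata.X),
            coordinates=np.asarray(adata.obsm[SPATIAL_KEY], dtype=float),
            slice_id=np.asarray(adata.obs[SLICE_KEY].astype(str)),
            var_names=np.asarray(adata.var_names, dtype=object),
            obs=obs,
            unit_scale=float(adata.uns.get("unit_scale", 1.0)),
            **kwargs,
        )

    # -- persistence -----------------------------------------------------
    def write_h5ad(self, path) -> None:
        self.to_anndata().write_h5ad(Path(path))

    def write_tables(self, directory) -> None:
        """Write expression.mtx + cells.csv + genes.csv into ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        from scipy.io import mmwrite

        X = self.expression if sp.issparse(self.expression) else sp.csr_matrix(self.expression)
        mmwrite(directory / "expression.mtx", X)
        cells = pd.DataFrame(self.coordinates, columns=list("xyz")[: self.coordinates.shape[1]])
        cells[SLICE_KEY] = self.slice_id.astype(str)
        for col in _LABEL_COLUMNS:
            val = getattr(self, col)
            if val is not None:
                cells[col] = np.asarray(val).astype(str)
        if self.obs is not None:
            for col in self.obs.columns:
                cells[col] = np.asarray(self.obs[col])
        cells.to_csv(directory / "cells.csv", index=False)
        pd.DataFrame({"gene": self.var_names}).to_csv(directory / "genes.csv", index=False)

    @classmethod
    def read_tables(cls, directory) -> "SpatialDataset":
        directory = Path(directory)
        from scipy.io import mmread

        mtx = directory / "expression.mtx"
        if mtx.exists():
            X = sp.csr_matrix(mmread(mtx))
        else:
            X = pd.read_csv(directory / "expression.csv", index_col=None).to_numpy(float)
        cells = pd.read_csv(directory / "cells.csv")
        if SLICE_KEY not in cells.columns:
            raise MissingSliceKeyError(
                f"multi-slice key absent: cells.csv needs a {SLICE_KEY!r} column"
            )
        coord_cols = [c for c in ("x", "y", "z") if c in cells.columns]
        coords = cells[coord_cols].to_numpy(float)
        if coords.shape[0] != X.shape[0]:
            raise ShapeMismatchError(
                f"expression has {X.shape[0]} rows but cells.csv has {coords.shape[0]}"
            )
        kwargs = {
            col: cells[col].astype(str).to_numpy() for col in _LABEL_COLUMNS if col in cells
        }
        genes_file = directory / "genes.csv"
        var_names = (
            pd.read_csv(genes_file)["gene"].to_numpy(object) if genes_file.exists() else None
        )
        extra = [
            c
            for c in cells.columns
            if c not in coord_cols and c != SLICE_KEY and c not in _LABEL_COLUMNS
        ]
        return cls(
            expression=X,
            coordinates=coords,
            slice_id=cells[SLICE_KEY].astype(str).to_numpy(),
            var_names=var_names,
            obs=cells[extra].copy() if extra else None,
            **kwargs,
        )


def load_dataset(path, format: Literal["h5ad", "tables"] | None = None) -> SpatialDataset:
    """Load a dataset from ``path`` in h5ad or plain-table format.

    ``format`` defaults to ``h5ad`` for ``.h5ad`` files and ``tables``
    for directories.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format is None:
        format = "h5ad" if path.suffix == ".h5ad" else "tables"
    if format == "h5ad":
        import anndata as ad

        return SpatialDataset.from_anndata(ad.read_h5ad(path))
    if format == "tables":
        return SpatialDataset.read_tables(path)
    raise ValueError(f"unknown format {format!r}")


def save_dataset(ds: SpatialDataset, path, format: Literal["h5ad", "tables"] | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "h5ad" if path.suffix == ".h5ad" else "tables"
    if format == "h5ad":
        ds.write_h5ad(path)
    elif format == "tables":
        ds.write_tables(path)
    else:
        raise ValueError(f"unknown format {format!r}")


def validate(ds: SpatialDataset) -> ValidationReport:
    """Check a dataset for the problems that break the pipeline.

    Reports (never raises): NaN coordinates (error), negative expression
    entries (warning — normalized/scaled inputs are not expected here),
    empty slices (error) and duplicate feature names (warning).
    Validation is pure: repeated calls give identical reports.
    """
    report = ValidationReport()
    bad = np.where(~np.isfinite(ds.coordinates).all(axis=1))[0]
    if bad.size:
        report.issues.append(
            ValidationIssue(
                "error",
                f"non-finite coordinates for {bad.size} cell(s), first at index {bad[0]}",
                bad.tolist(),
            )
        )
    X = ds.expression
    neg = (X < 0).sum() if not sp.issparse(X) else (X.data < 0).sum()
    if neg:
        report.issues.append(
            ValidationIssue("warning", f"{int(neg)} negative expression entries")
        )
    counts = pd.Series(ds.slice_id).value_counts()
    empty = counts[counts == 0]
    if len(empty):
        report.issues.append(
            ValidationIssue("error", f"empty slices: {list(empty.index)}")
        )
    names = pd.Series(ds.var_names)
    dup = names[names.duplicated()].unique()
    if len(dup):
        report.issues.append(
            ValidationIssue(
                "warning", f"duplicate feature names: {list(dup[:5])}"
            )
        )
    labels = pd.Series(ds.slice_id)
    if labels.isna().any():
        idx = np.where(labels.isna())[0]
        report.issues.append(
            ValidationIssue("error", "missing slice_id values", idx.tolist())
        )
    return report
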
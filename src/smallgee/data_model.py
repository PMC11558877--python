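"""Long-format data handling: design encoding and per-cluster blocks.

Clustered or longitudinal binary data arrive as one row per observation with a
cluster identifier, an optional within-cluster occasion label, a 0/1 outcome and
covariates.  This module expands a model formula into a design matrix (treatment
coding, intercept always included) and regroups rows into per-cluster blocks in
occasion order, which is the shape every estimating-equation routine consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy

from .errors import (
    DataError,
    OccasionCollisionError,
    OrderingError,
    SpecificationError,
)

logger = logging.getLogger(__name__)

__all__ = ["ClusterBlock", "DesignData", "encode_design", "build_clusters", "read_table"]


@dataclass
class ClusterBlock:
    """One cluster's slice of the data.

    Attributes
    ----------
    cluster_id : hashable
        Label of the cluster.
    y : ndarray, shape (n_i,)
        Binary outcomes, in occasion order.
    X : ndarray, shape (n_i, p)
        Design-matrix rows for this cluster.
    occasions : ndarray, shape (n_i,)
        Occasion labels (categorical; within-cluster measurement positions
        when no occasion column was supplied).
    positions : ndarray of int, shape (n_i,)
        Indices of the occasions in the pooled, sorted occasion set.  These
        index the pooled T x T matrix of an unstructured working correlation
        and define adjacency for AR(1).
    """

    cluster_id: object
    y: np.ndarray
    X: np.ndarray
    occasions: np.ndarray
    positions: np.ndarray

    @property
    def n(self) -> int:
        return self.y.shape[0]


@dataclass
class DesignData:
    """Formula-encoded dataset ready for clustering.

    ``frame`` holds the retained (complete-case) rows of the original data;
    ``y``/``X`` are aligned with it row for row.
    """

    y: np.ndarray
    X: np.ndarray
    column_names: list[str]
    frame: pd.DataFrame
    outcome_name: str
    n_dropped: int = 0
    blocks: list[ClusterBlock] = field(default_factory=list)
    n_occasions: int = 0

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_clusters(self) -> int:
        return len(self.blocks)


def read_table(path, delimiter: str = ",") -> pd.DataFrame:
    """Read a delimited text file with a header row into a DataFrame."""
    try:
        df = pd.read_csv(path, delimiter=delimiter)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DataError(f"cannot read data file {path!r}: {exc}") from exc
    if df.shape[1] < 2:
        raise DataError(
            f"file {path!r} parsed to {df.shape[1]} column(s); check the delimiter"
        )
    return df


def encode_design(formula: str, data: pd.DataFrame) -> DesignData:
    """Expand ``outcome ~ terms`` into outcome vector and design matrix.

    Categorical terms (marked ``C(name)`` in the formula, or string-valued
    columns) are treatment-coded against the lowest-sorted level; an intercept
    column is always prepended.  Rows with missing values in the outcome or any
    model term are dropped (count logged and recorded).
    """
    if "~" not in formula:
        raise SpecificationError(f"formula {formula!r} lacks an outcome (no '~')")
    try:
        y_df, x_df = patsy.dmatrices(formula, data, return_type="dataframe")
    except patsy.PatsyError as exc:
        raise SpecificationError(f"cannot build design from {formula!r}: {exc}") from exc

    info = x_df.design_info
    for term, sl in info.term_name_slices.items():
        if term != "Intercept" and sl.stop == sl.start:
            # a one-level factor is treatment-coded away entirely
            raise SpecificationError(
                f"term {term!r} is degenerate (single level); it contributes "
                "no design columns"
            )
    y = np.asarray(y_df).ravel()
    bad = ~np.isin(y, (0.0, 1.0))
    if bad.any():
        raise DataError(
            f"outcome {y_df.columns[0]!r} must be coded 0/1; "
            f"found value(s) {sorted(set(y[bad]))[:5]}"
        )

    kept = x_df.index
    n_dropped = len(data) - len(kept)
    if n_dropped:
        logger.info("dropped %d incomplete row(s) (missing outcome or model term)", n_dropped)
    frame = data.loc[kept]
    return DesignData(
        y=y.astype(float),
        X=np.asarray(x_df, dtype=float),
        column_names=list(x_df.columns),
        frame=frame,
        outcome_name=str(y_df.columns[0]),
        n_dropped=n_dropped,
    )


def build_clusters(design: DesignData, id: str, repeated: str | None = None) -> DesignData:
    """Split encoded rows into per-cluster blocks.

    With ``repeated`` given, rows are sorted within each cluster by occasion
    label (occasions are categorical positions, not numeric times) and labels
    must be unique within a cluster.  Without it, observations of a cluster
    must occupy contiguous rows and occasions are the within-cluster row
    positions.
    """
    frame = design.frame
    if id not in frame.columns:
        raise DataError(f"id column {id!r} not found in data")
    ids = frame[id]
    if ids.isna().any():
        raise DataError(f"id column {id!r} contains missing values")

    if repeated is not None and repeated not in frame.columns:
        raise DataError(f"repeated column {repeated!r} not found in data")

    codes, uniques = pd.factorize(ids, use_na_sentinel=False)
    if repeated is None:
        # ids must form contiguous runs: the first row of each run is a new code
        new_run = np.flatnonzero(np.diff(codes, prepend=codes[0] - 1) != 0)
        if len(new_run) != len(uniques):
            raise OrderingError(
                "cluster rows are not contiguous; supply the occasion column "
                "or sort the data by cluster"
            )

    blocks: list[ClusterBlock] = []
    if repeated is not None:
        occ_all = frame[repeated]
        if occ_all.isna().any():
            raise DataError(f"repeated column {repeated!r} contains missing values")
        pooled = np.array(sorted(pd.unique(occ_all)))
        pos_of = {lab: t for t, lab in enumerate(pooled)}
        n_occasions = len(pooled)
    else:
        n_occasions = 0

    for k, cid in enumerate(uniques):
        idx = np.flatnonzero(codes == k)
        if repeated is not None:
            occ = np.asarray(frame[repeated].iloc[idx])
            if len(set(occ.tolist())) != len(occ):
                raise OccasionCollisionError(
                    f"cluster {cid!r} has duplicated occasion label(s)"
                )
            positions = np.array([pos_of[o] for o in occ])
            order = np.argsort(positions, kind="stable")
            idx = idx[order]
            occ = occ[order]
            positions = positions[order]
        else:
            occ = np.arange(len(idx))
            positions = occ.copy()
            n_occasions = max(n_occasions, len(idx))
        blocks.append(
            ClusterBlock(
                cluster_id=cid,
                y=design.y[idx],
                X=design.X[idx],
                occasions=occ,
                positions=positions,
            )
        )

    design.blocks = blocks
    design.n_occasions = n_occasions
    return design


def prepare(
    data: pd.DataFrame, formula: str, id: str, repeated: str | None = None
) -> DesignData:
    """Convenience wrapper: complete-case filter on id/repeated, encode, cluster."""
    cols = [c for c in (id, repeated) if c is not None]
    for c in cols:
        if c not in data.columns:
            raise DataError(f"column {c!r} not found in data")
    design = encode_design(formula, data)
    return build_clusters(design, id=id, repeated=repeated)
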
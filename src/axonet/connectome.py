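"""Connectivity matrices, quality control, and on-disk formats.

A :class:`ConnectivityMatrix` is a symmetric node-by-node edge-weight
matrix with zero diagonal; the weight kind is either FA (fractional
anisotropy, per-edge mean in [0, 1]) or NOS (number of streamlines,
non-negative counts). Matrices are stored dense (labeled CSV) or sparse
(matrix-market upper triangle with a label sidecar).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = ["ConnectivityMatrix", "QCReport", "qc_connectomes",
           "read_connectome", "write_connectome"]

_SYMMETRY_TOL = 1e-9


class ConnectivityMatrix:
    """Symmetric edge-weight matrix with node labels.

    Parameters
    ----------
    values : (n, n) array
        Symmetric with zero diagonal (enforced within floating tolerance).
    weight_kind : {"FA", "NOS"}
    labels : sequence of str, optional
        Node labels; defaults to ``node_0001``...
    """

    def __init__(self, values, weight_kind: str, labels=None):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if np.abs(values - values.T).max(initial=0.0) > _SYMMETRY_TOL:
            raise ValueError("connectivity matrix is asymmetric beyond tolerance")
        if weight_kind not in ("FA", "NOS"):
            raise ValueError(f"unknown weight_kind {weight_kind!r}")
        values = 0.5 * (values + values.T)
        np.fill_diagonal(values, 0.0)
        if weight_kind == "FA" and (values.min() < 0 or values.max() > 1):
            raise ValueError("FA weights must lie in [0, 1]")
        if weight_kind == "NOS" and values.min() < 0:
            raise ValueError("NOS weights must be non-negative")
        self.values = values
        self.weight_kind = weight_kind
        n = values.shape[0]
        self.labels = list(labels) if labels is not None \
            else [f"node_{i + 1:04d}" for i in range(n)]
        if len(self.labels) != n:
            raise ValueError("label count does not match matrix dimension")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def upper_values(self) -> np.ndarray:
        """Edge weights in fixed upper-triangle order."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.values[iu]

    def __getitem__(self, key):
        return self.values[key]

    def __repr__(self):
        return (f"ConnectivityMatrix(n_nodes={self.n_nodes}, "
                f"weight_kind={self.weight_kind!r})")


@dataclass
class QCReport:
    """Per-participant connectome quality-control summary."""
    missing_fraction: pd.Series
    outlier_edges: pd.Series
    passed: pd.Series
    edge_mask: dict[str, np.ndarray]
    params: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "missing_fraction": self.missing_fraction,
            "outlier_edges": self.outlier_edges,
            "passed": self.passed,
        })


def qc_connectomes(
    matrices: dict[str, ConnectivityMatrix],
    groups: pd.Series | dict[str, str],
    presence_threshold: float = 0.6,
    outlier_sd: float = 3.0,
    max_missing_fraction: float = 0.1,
) -> QCReport:
    """Missing-edge and outlier screening against the group edge mask.

    The group edge mask keeps edges with non-zero weight in at least
    ``presence_threshold`` of the group's participants. Per participant,
    the missing fraction is the share of mask edges absent from their
    matrix, and an edge weight is an outlier when it deviates more than
    ``outlier_sd`` SDs from the leave-one-out group edge mean (so an
    extreme value cannot mask itself by inflating the group SD; outlier
    screening needs >= 3 per group and is skipped below that).
    Participants exceeding ``max_missing_fraction`` fail.
    """
    if not 0 < presence_threshold <= 1:
        raise ValueError("presence_threshold must be in (0, 1]")
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series)
                       else groups)
    if set(groups.index) != set(matrices):
        raise ValueError("group labels and matrices name different participants")
    logger.info("QC with presence_threshold=%s outlier_sd=%s max_missing=%s",
                presence_threshold, outlier_sd, max_missing_fraction)

    missing, outliers, edge_masks = {}, {}, {}
    for g in groups.unique():
        pids = groups.index[groups == g]
        if len(pids) < 2:
            raise ValueError(f"group {g!r} needs >= 2 participants for QC")
        stack = np.stack([matrices[p].upper_values() for p in pids])
        present = stack != 0
        mask = present.mean(axis=0) >= presence_threshold
        edge_masks[g] = mask
        sub = stack[:, mask]
        n_mask = int(mask.sum())
        g = len(pids)
        # leave-one-out group statistics: a participant's own extreme edge
        # must not mask itself by inflating the group SD
        tot = sub.sum(axis=0)
        totsq = (sub**2).sum(axis=0)
        for i, p in enumerate(pids):
            missing[p] = float((~present[i, mask]).mean()) if n_mask else 0.0
            if g < 3:
                outliers[p] = 0
                continue
            mu = (tot - sub[i]) / (g - 1)
            var = np.maximum(
                (totsq - sub[i]**2 - (g - 1) * mu**2) / (g - 2), 0.0)
            sd = np.sqrt(var)
            with np.errstate(invalid="ignore", divide="ignore"):
                dev = np.abs(sub[i] - mu) > outlier_sd * sd
            outliers[p] = int(np.nansum(np.where(sd > 0, dev, False)))
    missing = pd.Series(missing, name="missing_fraction")
    outliers = pd.Series(outliers, name="outlier_edges")
    passed = missing <= max_missing_fraction
    return QCReport(missing, outliers, passed.rename("passed"), edge_masks,
                    params=dict(presence_threshold=presence_threshold,
                                outlier_sd=outlier_sd,
                                max_missing_fraction=max_missing_fraction))


def write_connectome(path, matrix: ConnectivityMatrix, sparse: bool = False) -> None:
    """Write a matrix as labeled dense CSV or matrix-market upper triangle.

    The sparse form stores only the strict upper triangle; node labels go
    to a ``<path>.labels`` sidecar (one per line, first line ``#KIND``).
    """
    path = Path(path)
    if sparse:
        coo = scipy.sparse.coo_matrix(np.triu(matrix.values, k=1))
        scipy.io.mmwrite(str(path), coo)
        side = path.with_suffix(path.suffix + ".labels")
        side.write_text("\n".join([f"#{matrix.weight_kind}"] + matrix.labels)
                        + "\n")
    else:
        df = pd.DataFrame(matrix.values, index=matrix.labels,
                          columns=matrix.labels)
        df.index.name = f"#{matrix.weight_kind}"
        df.to_csv(path)


def read_connectome(path, weight_kind: str | None = None,
                    n_nodes: int | None = None) -> ConnectivityMatrix:
    """Read a matrix written by :func:`write_connectome`.

    Symmetry is enforced on read for the dense form (asymmetry beyond 1e-9
    is an error); the sparse upper-triangle form is mirrored.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        vals = scipy.io.mmread(str(path)).toarray()
        if np.tril(vals, k=-1).any():
            raise ValueError(f"{path}: sparse connectome must be upper triangle")
        vals = vals + vals.T
        labels = None
        side = path.with_suffix(path.suffix + ".labels")
        if side.exists():
            lines = side.read_text().splitlines()
            if lines and lines[0].startswith("#"):
                weight_kind = weight_kind or lines[0][1:]
                lines = lines[1:]
            labels = lines
    else:
        df = pd.read_csv(path, index_col=0)
        if df.index.name and str(df.index.name).startswith("#"):
            weight_kind = weight_kind or str(df.index.name)[1:]
        vals = df.to_numpy(dtype=float)
        labels = list(df.columns)
    if weight_kind is None:
        raise ValueError(f"{path}: weight kind not stored and not given")
    if n_nodes is not None and vals.shape[0] != n_nodes:
        raise ValueError(f"{path}: expected {n_nodes} nodes, found "
                         f"{vals.shape[0]}")
    return ConnectivityMatrix(vals, weight_kind=weight_kind, labels=labels)
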
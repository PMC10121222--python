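"""Structural connectome handling: coupling and delay matrices.

The network model couples regional neural masses through a rescaled graph
Laplacian of the streamline-weight matrix.  Rescaling proceeds in two steps:

1. ``L = W - diag(rowsum(W))`` — subtracting each row sum from the diagonal
   sets every node's weighted in-degree to zero;
2. scalar division of all entries by a matrix norm (Frobenius by default).

The result is linearly stable: all eigenvalues have non-positive real part,
with exactly one zero eigenvalue (per connected component).  Conduction
delays are ``lengths / velocity`` with mm and m/s yielding ms directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConnectomeError, ParameterError

logger = logging.getLogger(__name__)

#: Canonical 7-network parcellation labels used for region grouping.
YEO7_NETWORKS = ("VISN", "SMN", "DAN", "ASN", "LIMN", "FPN", "DMN")


@dataclass
class ConnectomeGraph:
    """A validated structural network with derived coupling and delays.

    Attributes
    ----------
    weights : (N, N) ndarray
        Non-negative streamline weights, zero diagonal (dimensionless).
    lengths : (N, N) ndarray
        Fiber tract lengths in mm, zero diagonal.
    velocity : float
        Global axonal conduction velocity in m/s.
    coupling : (N, N) ndarray
        Rescaled Laplacian coupling matrix (rows sum to zero).
    delays : (N, N) ndarray
        Conduction delays in ms, ``lengths / velocity``.
    region_labels : list of str
    network_assignment : list of str
        One canonical network label per region.
    """

    weights: np.ndarray
    lengths: np.ndarray
    velocity: float
    coupling: np.ndarray = field(default=None)  # type: ignore[assignment]
    delays: np.ndarray = field(default=None)  # type: ignore[assignment]
    region_labels: list[str] = field(default=None)  # type: ignore[assignment]
    network_assignment: list[str] = field(default=None)  # type: ignore[assignment]
    norm: str = "frobenius"

    def __post_init__(self):
        self.weights = _validate_square(np.asarray(self.weights, dtype=float),
                                        "weights")
        self.lengths = _validate_square(np.asarray(self.lengths, dtype=float),
                                        "lengths")
        if self.weights.shape != self.lengths.shape:
            raise InvalidConnectomeError(
                f"weights shape {self.weights.shape} != lengths shape "
                f"{self.lengths.shape}")
        n = self.n_regions
        if self.coupling is None:
            self.coupling = laplacian_rescale(self.weights, norm=self.norm)
        if self.delays is None:
            self.delays = delays_from_lengths(self.lengths, self.velocity)
        if self.region_labels is None:
            self.region_labels = [f"region_{i:03d}" for i in range(n)]
        if self.network_assignment is None:
            self.network_assignment = [YEO7_NETWORKS[i % 7] for i in range(n)]
        if len(self.region_labels) != n or len(self.network_assignment) != n:
            raise InvalidConnectomeError(
                "region_labels / network_assignment length mismatch with "
                f"matrix size {n}")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


def _validate_square(mat: np.ndarray, name: str) -> np.ndarray:
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise InvalidConnectomeError(f"{name} must be square, got {mat.shape}")
    bad = np.argwhere(~np.isfinite(mat))
    if bad.size:
        r, c = bad[0]
        raise InvalidConnectomeError(
            f"{name} has a non-finite entry at row {r}, col {c}")
    if (mat < 0).any():
        r, c = np.argwhere(mat < 0)[0]
        raise InvalidConnectomeError(
            f"{name} has a negative entry at row {r}, col {c}")
    if np.any(np.diag(mat) != 0):
        # tractography exports occasionally carry self-connections; drop them
        logger.warning("%s has nonzero diagonal entries; zeroing "
                       "self-connections", name)
        mat = mat.copy()
        np.fill_diagonal(mat, 0.0)
    return mat


def laplacian_rescale(weights: np.ndarray, norm: str = "frobenius") -> np.ndarray:
    """Rescaled Laplacian coupling matrix ``L / ||L||``.

    ``L = W - diag(rowsum(W))``: each row sums to zero, the diagonal is
    non-positive, and for any non-negative ``W`` the spectrum satisfies
    ``Re(lambda) <= 0`` with a zero eigenvalue for the constant vector.

    Parameters
    ----------
    weights : (N, N) array_like
        Non-negative, zero-diagonal connection weights.  Asymmetric input is
        accepted; row sums are computed on the matrix as given.
    norm : {"frobenius", "spectral"}
        Matrix norm used for the scalar division.

    Returns
    -------
    (N, N) ndarray
        The rescaled Laplacian; all-zero input returns an all-zero matrix.
    """
    w = _validate_square(np.asarray(weights, dtype=float), "weights")
    lap = w - np.diag(w.sum(axis=1))
    if norm == "frobenius":
        scale = np.linalg.norm(lap, "fro")
    elif norm == "spectral":
        scale = np.linalg.norm(lap, 2)
    else:
        raise ParameterError(f"unknown matrix norm {norm!r}; "
                             "expected 'frobenius' or 'spectral'")
    if scale == 0.0:
        return lap
    return lap / scale


def delays_from_lengths(lengths: np.ndarray, velocity: float) -> np.ndarray:
    """Conduction delay matrix in ms from tract lengths (mm) and velocity (m/s).

    mm / (m/s) = ms, so no further unit conversion is needed.
    """
    if velocity <= 0:
        raise ParameterError(f"conduction velocity must be > 0, got {velocity}")
    lengths = np.asarray(lengths, dtype=float)
    if (lengths < 0).any():
        raise InvalidConnectomeError("tract lengths must be non-negative")
    return lengths / float(velocity)


def load_connectome(weights_path, lengths_path, velocity: float,
                    labels_path=None, norm: str = "frobenius") -> ConnectomeGraph:
    """Read weights/lengths matrices (tab-delimited text) and build a graph.

    Matrix files may carry a header row of region labels.  The labels file,
    if given, has one ``label<TAB>network`` pair per line and overrides any
    header labels.
    """
    weights, wlabels = read_matrix(weights_path)
    lengths, llabels = read_matrix(lengths_path)
    if weights.shape != lengths.shape:
        raise InvalidConnectomeError(
            f"shape mismatch between {weights_path} {weights.shape} and "
            f"{lengths_path} {lengths.shape}")
    labels = wlabels or llabels
    networks = None
    if labels_path is not None:
        df = pd.read_csv(labels_path, sep="\t", header=None,
                         names=["label", "network"])
        labels = df["label"].astype(str).tolist()
        networks = df["network"].astype(str).tolist()
        if len(labels) != weights.shape[0]:
            raise InvalidConnectomeError(
                f"labels file {labels_path} has {len(labels)} entries for a "
                f"{weights.shape[0]}-region matrix")
    return ConnectomeGraph(weights=weights, lengths=lengths,
                           velocity=velocity, region_labels=labels,
                           network_assignment=networks, norm=norm)


def read_matrix(path) -> tuple[np.ndarray, list[str] | None]:
    """Read a tab-delimited matrix with an optional header row of labels."""
    with open(path) as fh:
        first = fh.readline()
    tokens = first.rstrip("\n").split("\t")
    has_header = any(not _is_number(tok) for tok in tokens if tok != "")
    if has_header:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        labels = [str(c) for c in df.columns]
        mat = df.to_numpy(dtype=float)
    else:
        labels = None
        mat = pd.read_csv(path, sep="\t", header=None,
                          float_precision="round_trip").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(mat))
    if bad.size:
        r, c = bad[0]
        raise InvalidConnectomeError(
            f"{path}: non-finite value at row {r}, col {c}")
    return mat, labels


def write_connectome(graph: ConnectomeGraph, weights_path, lengths_path,
                     labels_path=None) -> None:
    """Write a graph back to the tab-delimited exchange format."""
    header = "\t".join(graph.region_labels)
    for mat, path in ((graph.weights, weights_path),
                      (graph.lengths, lengths_path)):
        np.savetxt(path, mat, delimiter="\t", header=header, comments="",
                   fmt="%.17g")
    if labels_path is not None:
        with open(labels_path, "w") as fh:
            for lab, net in zip(graph.region_labels, graph.network_assignment):
                fh.write(f"{lab}\t{net}\n")


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True
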
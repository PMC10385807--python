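"""Sensor arrays and the internal/external multipole signal-vector basis.

The SSS basis for an N-channel array is the pair of matrices ``S_in``
(N x N_in) and ``S_out`` (N x N_out) whose columns are the sensor-space
signal patterns of the internal and external multipole terms, truncated at
degrees ``L_in`` and ``L_out``.  Columns are ordered l-major with m running
from -l to +l, and each stored column is normalised to unit Euclidean norm;
the pre-normalisation norms are kept so reconstructions can be expressed in
physical field units.

Any measured signal vector is modelled as ``phi = S_in x_in + S_out x_out``;
estimating the weights and keeping only the internal part separates fields
of sources inside the helmet from environmental interference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence

import numpy as np
import scipy.linalg

from .exceptions import DegenerateBasisError
from .harmonics import HarmonicIndex, internal_term_field, external_term_field, iter_indices, n_terms

__all__ = [
    "SensorArray",
    "MultipoleBasis",
    "ndims",
    "build_basis",
    "truncate_basis",
    "condition_number",
    "subspace_angles",
    "mean_subspace_angle",
    "read_geometry",
    "write_geometry",
]

_GEOMETRY_COLUMNS = ["label", "x", "y", "z", "ox", "oy", "oz"]


@dataclass
class SensorArray:
    """Point-magnetometer array: positions, unit orientations and labels.

    The expansion origin defaults to the centre of mass of the sensor
    positions, the natural choice for a rigid helmet.
    """

    positions: np.ndarray  # (N, 3) metres
    orientations: np.ndarray  # (N, 3) unit vectors
    labels: List[str] = field(default_factory=list)
    origin: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.orientations = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        if self.positions.shape != self.orientations.shape or self.positions.shape[1] != 3:
            raise ValueError("positions and orientations must both be (N, 3)")
        n = self.positions.shape[0]
        if n < 1:
            raise ValueError("need at least one channel")
        norms = np.linalg.norm(self.orientations, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-10):
            raise ValueError("orientation vectors must have unit norm (tol 1e-10)")
        if not self.labels:
            self.labels = [f"ch{i:03d}" for i in range(n)]
        if len(self.labels) != n:
            raise ValueError("label count must match channel count")
        if self.origin is None:
            self.origin = self.positions.mean(axis=0)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    def translated(self, offset) -> "SensorArray":
        """Rigidly translate the array (and its origin) by ``offset``."""
        off = np.asarray(offset, dtype=float)
        return SensorArray(
            self.positions + off, self.orientations.copy(), list(self.labels), self.origin + off
        )


@dataclass
class MultipoleBasis:
    """Column-normalised internal/external SSS basis for one array.

    ``S_in[:, j]`` is the unit-norm signal vector of internal term
    ``index_in[j]``; ``norms_in[j]`` is the Euclidean norm the column had
    before normalisation (same for the external side).
    """

    S_in: np.ndarray
    S_out: np.ndarray
    index_in: List[HarmonicIndex]
    index_out: List[HarmonicIndex]
    norms_in: np.ndarray
    norms_out: np.ndarray
    L_in: int
    L_out: int
    origin: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.S_in.shape[0]

    @property
    def n_in(self) -> int:
        return self.S_in.shape[1]

    @property
    def n_out(self) -> int:
        return self.S_out.shape[1]

    @property
    def S(self) -> np.ndarray:
        """Concatenated basis ``[S_in S_out]``."""
        return np.hstack([self.S_in, self.S_out])

    def internal_degree_slice(self, l: int) -> slice:
        """Column slice of ``S_in`` holding the 2l+1 degree-l terms."""
        if not 1 <= l <= self.L_in:
            raise ValueError(f"degree l={l} outside 1..{self.L_in}")
        start = l * l - 1  # sum of 2k+1 for k < l
        return slice(start, start + 2 * l + 1)


def ndims(l_in: int, l_out: int) -> int:
    """Total number of basis vectors, ``(L_in+1)**2 + (L_out+1)**2 - 2``.

    A pseudo-inverse of the full basis requires this to be at most the
    number of channels; the iterative solver only requires it per partial
    basis.
    """
    if l_in < 1 or l_out < 1:
        raise ValueError("truncation degrees must be >= 1")
    return (l_in + 1) ** 2 + (l_out + 1) ** 2 - 2


def _signal_columns(array: SensorArray, l_max: int, field_fn, kind: str):
    indices = list(iter_indices(l_max))
    cols = np.empty((array.n_channels, len(indices)))
    for j, idx in enumerate(indices):
        b = field_fn(idx, array.positions, array.origin)
        cols[:, j] = np.einsum("ij,ij->i", b, array.orientations)
    norms = np.linalg.norm(cols, axis=0)
    for j, idx in enumerate(indices):
        if norms[j] == 0 or not np.isfinite(norms[j]):
            raise DegenerateBasisError(idx.l, idx.m, kind)
    return cols / norms, indices, norms


def build_basis(array: SensorArray, l_in: int, l_out: int) -> MultipoleBasis:
    """Assemble the column-normalised SSS basis of an array.

    Over-complete bases (``ndims > N``) are allowed here; only solvers that
    invert the full basis reject them.
    """
    ndims(l_in, l_out)  # validates degrees
    s_in, idx_in, norms_in = _signal_columns(array, l_in, internal_term_field, "internal")
    s_out, idx_out, norms_out = _signal_columns(array, l_out, external_term_field, "external")
    return MultipoleBasis(
        S_in=s_in,
        S_out=s_out,
        index_in=idx_in,
        index_out=idx_out,
        norms_in=norms_in,
        norms_out=norms_out,
        L_in=l_in,
        L_out=l_out,
        origin=array.origin.copy(),
    )


def truncate_basis(basis: MultipoleBasis, l_in: int, l_out: int) -> MultipoleBasis:
    """Restrict a basis to lower truncation degrees by slicing columns.

    Because columns are l-major and normalised independently, the truncated
    basis is numerically identical to one built directly at the lower
    degrees.
    """
    if l_in > basis.L_in or l_out > basis.L_out:
        raise ValueError("cannot truncate to higher degrees than built")
    ndims(l_in, l_out)
    k_in, k_out = n_terms(l_in), n_terms(l_out)
    return MultipoleBasis(
        S_in=basis.S_in[:, :k_in],
        S_out=basis.S_out[:, :k_out],
        index_in=basis.index_in[:k_in],
        index_out=basis.index_out[:k_out],
        norms_in=basis.norms_in[:k_in],
        norms_out=basis.norms_out[:k_out],
        L_in=l_in,
        L_out=l_out,
        origin=basis.origin,
    )


def condition_number(basis: MultipoleBasis) -> float:
    """2-norm condition number (largest/smallest singular value) of
    the concatenated column-normalised basis ``[S_in S_out]``."""
    s = np.linalg.svd(basis.S, compute_uv=False)
    if s[-1] == 0:
        return np.inf
    return float(s[0] / s[-1])


def subspace_angles(basis: MultipoleBasis) -> np.ndarray:
    """Principal angles (degrees, descending) between span(S_in) and
    span(S_out); larger angles mean the two subspaces are easier to
    separate."""
    return np.degrees(scipy.linalg.subspace_angles(basis.S_in, basis.S_out))


def mean_subspace_angle(basis: MultipoleBasis, method: str = "principal") -> float:
    """Mean angle between the internal and external subspaces.

    ``method='principal'`` averages the principal angles between the two
    column spans; ``method='pairwise'`` averages the angles between every
    internal/external column pair.  Both are exposed because "the" subspace
    angle of an array is quoted inconsistently in the literature.
    """
    if method == "principal":
        return float(np.mean(subspace_angles(basis)))
    if method == "pairwise":
        cos = np.clip(np.abs(basis.S_in.T @ basis.S_out), 0.0, 1.0)
        return float(np.degrees(np.mean(np.arccos(cos))))
    raise ValueError("method must be 'principal' or 'pairwise'")


# --- geometry file round-tripping ------------------------------------------

def write_geometry(array: SensorArray, path) -> None:
    """Write sensor geometry as CSV (``label,x,y,z,ox,oy,oz``) or JSON.

    Floats are written with shortest round-trip precision so that
    read -> write reproduces the text bit-exactly.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "labels": list(array.labels),
            "positions": array.positions.tolist(),
            "orientations": array.orientations.tolist(),
            "origin": array.origin.tolist(),
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return
    lines = [",".join(_GEOMETRY_COLUMNS)]
    for lab, p, o in zip(array.labels, array.positions, array.orientations):
        nums = [repr(float(v)) for v in (*p, *o)]
        lines.append(",".join([lab, *nums]))
    path.write_text("\n".join(lines) + "\n")


def read_geometry(path) -> SensorArray:
    """Read sensor geometry written by :func:`write_geometry`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        return SensorArray(
            np.asarray(payload["positions"], dtype=float),
            np.asarray(payload["orientations"], dtype=float),
            list(payload["labels"]),
            np.asarray(payload["origin"], dtype=float) if payload.get("origin") is not None else None,
        )
    labels: List[str] = []
    rows: List[Sequence[float]] = []
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if header != _GEOMETRY_COLUMNS:
            raise ValueError(f"unexpected geometry header {header!r}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.strip().split(",")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    arr = np.asarray(rows, dtype=float)
    return SensorArray(arr[:, :3], arr[:, 3:], labels)
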
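"""Standard pseudo-inverse SSS and the iterative partial-basis solver.

Standard SSS estimates all multipole weights at once, ``x = S^+ phi``, which
requires the basis dimension to be at most the channel count and becomes
numerically unstable as the two approach parity — exactly the regime of
current low-channel-count magnetometer arrays at the high truncation orders
their sensor proximity demands.

The iterative solver exploits the hierarchy of the expansion (low degrees
carry most of the signal energy, distal interference above all): it sweeps
the internal degrees ``l = 1..L_in`` in ascending order, and for each degree
solves a small, well-conditioned least-squares problem on the *partial
basis* — the 2l+1 degree-l internal columns concatenated with all external
columns — against the residual of everything estimated so far.  The external
weights are re-estimated in every partial solve (they are zeroed whenever a
residual is formed), and the whole sweep is cycled a fixed number of times.
At a fixed point the residual is orthogonal to every partial basis and hence
to the full basis, so on well-conditioned problems the iteration converges
to the joint least-squares solution; on ill-conditioned ones it remains
stable because no wide matrix is ever inverted.

Time samples are independent: a channels x samples matrix is processed as
independent right-hand sides sharing one set of factorisations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .exceptions import BasisTooLargeError, InvalidDataError
from .sss_basis import MultipoleBasis, ndims

__all__ = [
    "WeightVector",
    "IterationRecord",
    "SeparationResult",
    "standard_sss",
    "partial_basis",
    "iterative_sss",
]

#: Relative singular-value cutoff for every pseudo-inverse.  Deliberately
#: tiny: partial bases are well-conditioned by construction, and the
#: standard solver must *exhibit* its instability rather than mask it by
#: aggressive truncation.
RCOND = 1e-12


@dataclass
class WeightVector:
    """Multipole weights in the column-normalised frame.

    ``x_in`` is (N_in, T) and ``x_out`` (N_out, T) — one weight vector per
    time sample.  Index maps are shared with the basis that produced them.
    """

    x_in: np.ndarray
    x_out: np.ndarray

    def __post_init__(self) -> None:
        self.x_in = np.atleast_2d(np.asarray(self.x_in, dtype=float))
        self.x_out = np.atleast_2d(np.asarray(self.x_out, dtype=float))
        if self.x_in.shape[1] != self.x_out.shape[1]:
            raise ValueError("x_in and x_out must cover the same samples")

    @property
    def stacked(self) -> np.ndarray:
        return np.vstack([self.x_in, self.x_out])


@dataclass
class IterationRecord:
    """One completed sweep of the iterative solver."""

    iteration: int
    dx: float  # mean over samples of ||x_n - x_{n-1}||
    weights: Optional[WeightVector] = None  # snapshot, kept on request


@dataclass
class SeparationResult:
    """Weights, reconstructions and per-iteration history of one solve."""

    weights: WeightVector
    phi_in_hat: np.ndarray  # (N, T), field units of the input
    phi_out_hat: np.ndarray
    history: List[IterationRecord] = field(default_factory=list)


def _check_phi(basis: MultipoleBasis, phi) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    single = phi.ndim == 1
    phi = np.atleast_2d(phi.T).T if single else phi
    if phi.ndim != 2 or phi.shape[0] != basis.n_channels:
        raise InvalidDataError(
            f"signal must be (N={basis.n_channels}, T), got shape {phi.shape}"
        )
    if not np.all(np.isfinite(phi)):
        raise InvalidDataError("signal contains non-finite values")
    return phi


def standard_sss(basis: MultipoleBasis, phi) -> SeparationResult:
    """One-shot SSS via the pseudo-inverse of the full basis.

    Requires ``ndims(L_in, L_out) <= N``; the pseudo-inverse uses an SVD
    with relative cutoff ``RCOND``, so near-singular bases produce the
    characteristic noise amplification rather than an error.
    """
    nd = ndims(basis.L_in, basis.L_out)
    if nd > basis.n_channels:
        raise BasisTooLargeError(
            f"basis has {nd} columns but only {basis.n_channels} channels; "
            "use the iterative solver"
        )
    phi = _check_phi(basis, phi)
    x = np.linalg.pinv(basis.S, rcond=RCOND) @ phi
    weights = WeightVector(x[: basis.n_in], x[basis.n_in :])
    history = [IterationRecord(iteration=1, dx=float(np.mean(np.linalg.norm(x, axis=0))))]
    return SeparationResult(
        weights=weights,
        phi_in_hat=basis.S_in @ weights.x_in,
        phi_out_hat=basis.S_out @ weights.x_out,
        history=history,
    )


def partial_basis(basis: MultipoleBasis, l_in: int) -> np.ndarray:
    """Degree-``l_in`` internal columns concatenated with all external
    columns: the N x (2*l_in + 1 + N_out) matrix of one block update."""
    sl = basis.internal_degree_slice(l_in)  # validates the degree
    return np.hstack([basis.S_in[:, sl], basis.S_out])


def iterative_sss(
    basis: MultipoleBasis,
    phi,
    n_iterations: int = 5,
    initial: WeightVector | None = None,
    keep_weights: bool = False,
    dx_threshold: float | None = None,
) -> SeparationResult:
    """Iterative partial-basis SSS.

    Starting from zero weights (or ``initial``, which makes runs resumable
    at cycle boundaries), each cycle sweeps the internal degrees in
    ascending order; for each degree the residual is formed with the current
    degree's internal weights *and all external weights* zeroed, the partial
    basis is pseudo-inverted onto it, and both blocks are overwritten.  The
    final external weights are those of the last partial solve.  ``dx`` (the
    mean over samples of the Euclidean norm of the weight change) is
    recorded after every complete cycle; ``dx_threshold`` optionally stops
    early once dx falls below it, otherwise the fixed iteration count is
    honoured (non-convergence is not an error).
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    phi = _check_phi(basis, phi)
    n, t = phi.shape
    n_out = basis.n_out
    for l in range(1, basis.L_in + 1):
        if 2 * l + 1 + n_out > n:
            raise BasisTooLargeError(
                f"partial basis for degree {l} has {2 * l + 1 + n_out} columns "
                f"but only {n} channels"
            )

    pinvs = [np.linalg.pinv(partial_basis(basis, l), rcond=RCOND) for l in range(1, basis.L_in + 1)]

    if initial is None:
        x_in = np.zeros((basis.n_in, t))
        x_out = np.zeros((n_out, t))
    else:
        x_in = np.array(initial.x_in, dtype=float, copy=True)
        x_out = np.array(initial.x_out, dtype=float, copy=True)
        if x_in.shape != (basis.n_in, t) or x_out.shape != (n_out, t):
            raise InvalidDataError("initial weights do not match basis/signal shape")

    history: List[IterationRecord] = []
    for cycle in range(1, n_iterations + 1):
        x_prev = np.vstack([x_in, x_out])
        # recomputing the running internal prediction at each cycle start
        # keeps resumed runs bit-identical to uninterrupted ones
        pred_in = basis.S_in @ x_in
        for l in range(1, basis.L_in + 1):
            sl = basis.internal_degree_slice(l)
            block = basis.S_in[:, sl]
            resid = phi - pred_in + block @ x_in[sl]
            z = pinvs[l - 1] @ resid
            new_block = z[: 2 * l + 1]
            x_out = z[2 * l + 1 :]
            pred_in += block @ (new_block - x_in[sl])
            x_in[sl] = new_block
        dx = float(np.mean(np.linalg.norm(np.vstack([x_in, x_out]) - x_prev, axis=0)))
        history.append(
            IterationRecord(
                iteration=cycle,
                dx=dx,
                weights=WeightVector(x_in.copy(), x_out.copy()) if keep_weights else None,
            )
        )
        if dx_threshold is not None and dx < dx_threshold:
            break

    weights = WeightVector(x_in, x_out)
    return SeparationResult(
        weights=weights,
        phi_in_hat=basis.S_in @ x_in,
        phi_out_hat=basis.S_out @ x_out,
        history=history,
    )
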
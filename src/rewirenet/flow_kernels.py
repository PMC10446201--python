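"""Laplacians and consensus/advection kernels.

Signal traffic on the evolving digraph is modelled by linear node dynamics
x'(t) = -L x(t), with L the in-degree Laplacian (consensus: states converge
toward agreement) or the out-degree Laplacian (advection: directed transport
that conserves total concentration).  The matrix exponentials

    c(t) = expm(-L_in t)      (consensus kernel,  rows sum to 1)
    a(t) = expm(-L_out t)     (advection kernel,  columns sum to 1)

are the rewiring signal: entry (i, j) is the proportion of signal flow from
node j to node i via all paths over the interval t.  Kernel entries are
non-negative and entry (i, j) is positive exactly when j can reach i.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from .network_model import SpatialDigraph, _check_node

__all__ = [
    "KernelNumericalError",
    "laplacian",
    "kernel",
    "evolve_concentrations",
    "inflow_profile",
    "outflow_profile",
]

#: entrywise tolerance for kernel non-negativity; negatives beyond it are a
#: numerical failure, negatives within it are clamped to 0.
NEGATIVE_TOLERANCE = 1e-9


class KernelNumericalError(FloatingPointError):
    """Matrix exponential produced a non-finite or significantly negative kernel."""


def laplacian(g: SpatialDigraph, flavor: str) -> np.ndarray:
    """In-degree (D_in - A) or out-degree (D_out - A) Laplacian.

    In flavor: rows sum to 0 (D_in = diag of row sums).  Out flavor: columns
    sum to 0 (D_out = diag of column sums).  Off-diagonal entries are -A.
    """
    a = g.adjacency
    if flavor == "in":
        return np.diag(a.sum(axis=1)) - a
    if flavor == "out":
        return np.diag(a.sum(axis=0)) - a
    raise ValueError(f"flavor must be 'in' or 'out', got {flavor!r}")


def kernel(
    g: SpatialDigraph,
    flavor: str = "consensus",
    t: float = 1.0,
    neg_tol: float = NEGATIVE_TOLERANCE,
) -> np.ndarray:
    """Consensus kernel expm(-L_in t) or advection kernel expm(-L_out t).

    Computed by the dense scaling-and-squaring matrix exponential.  Entries
    with tiny negative round-off (within ``neg_tol``) are clamped to zero;
    anything worse, or a non-finite result, raises
    :class:`KernelNumericalError` since the exact kernels are provably
    non-negative.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if flavor == "consensus":
        L = laplacian(g, "in")
    elif flavor == "advection":
        L = laplacian(g, "out")
    else:
        raise ValueError(f"flavor must be 'consensus' or 'advection', got {flavor!r}")
    K = scipy.linalg.expm(-t * L)
    if not np.all(np.isfinite(K)):
        raise KernelNumericalError("non-finite kernel entries")
    if K.min() < -neg_tol:
        raise KernelNumericalError(f"kernel entry {K.min():.3e} below -{neg_tol:.1e}")
    np.clip(K, 0.0, None, out=K)
    return K


def evolve_concentrations(
    g: SpatialDigraph, x0: np.ndarray, t: float = 1.0, flavor: str = "consensus"
) -> np.ndarray:
    """Node concentrations after interval t: kernel(g, flavor, t) @ x0."""
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (g.n,):
        raise ValueError(f"x0 must have length n={g.n}")
    return kernel(g, flavor, t) @ x0


def inflow_profile(g: SpatialDigraph, v: int, t: float = 1.0) -> np.ndarray:
    """Intensity of in-flow to v: row v of the consensus kernel.

    Returns a length-n array; the self entry (index v) is set to NaN since v
    is never a rewiring candidate for itself.
    """
    _check_node(g, v)
    row = kernel(g, "consensus", t)[v].copy()
    row[v] = np.nan
    return row


def outflow_profile(g: SpatialDigraph, v: int, t: float = 1.0) -> np.ndarray:
    """Intensity of out-flow from v: column v of the advection kernel.

    Length-n array with the self entry NaN, as in :func:`inflow_profile`.
    """
    _check_node(g, v)
    col = kernel(g, "advection", t)[:, v].copy()
    col[v] = np.nan
    return col
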
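"""Absorbing-Markov-chain machinery: fixation probabilities and times.

Given the canonical blocks Q and R of the Moran chain, the fundamental
matrix F = (I - Q)^-1 collects the expected unconditional sojourn times
F[i, j] (time spent in transient state j starting from i).  From it follow

* absorption probabilities  Phi = F R          (columns: extinction, fixation)
* unconditional fixation times  tau_i = sum_j F[i, j]
* conditional sojourn times given eventual fixation,
      T_cond[i, j] = F[i, j] * phi_j / phi_i,   phi_i = Phi[i, fixation]
* conditional fixation times  tau_cond[i] = sum_j T_cond[i, j].

Closed forms for the well-mixed (complete-graph) special case serve as
independent oracles, and a numerical extrapolation helper evaluates
strong-selection (r -> infinity) limits.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
import scipy.linalg

from .chain import CanonicalChain, Number, wellmixed_transitions
from .graphs import Graph
from .states import StateSpace

__all__ = [
    "AbsorptionResult",
    "solve",
    "closed_form_fixation_probability",
    "closed_form_conditional_time",
    "start_averaged",
    "strong_selection_limit",
    "StartAveraged",
    "LimitResult",
]


def _exact_inverse(M: np.ndarray) -> np.ndarray:
    """Gauss-Jordan inverse over exact rationals (object array of Fraction)."""
    t = M.shape[0]
    A = [[Fraction(M[i, j]) for j in range(t)] for i in range(t)]
    inv = [[Fraction(int(i == j)) for j in range(t)] for i in range(t)]
    for col in range(t):
        pivot = next((k for k in range(col, t) if A[k][col] != 0), None)
        if pivot is None:
            raise np.linalg.LinAlgError("singular matrix: absorption not certain")
        A[col], A[pivot] = A[pivot], A[col]
        inv[col], inv[pivot] = inv[pivot], inv[col]
        p = A[col][col]
        A[col] = [x / p for x in A[col]]
        inv[col] = [x / p for x in inv[col]]
        for k in range(t):
            if k == col or A[k][col] == 0:
                continue
            f = A[k][col]
            A[k] = [a - f * b for a, b in zip(A[k], A[col])]
            inv[k] = [a - f * b for a, b in zip(inv[k], inv[col])]
    out = np.empty((t, t), dtype=object)
    out[:] = inv
    return out


@dataclass(frozen=True)
class AbsorptionResult:
    """Fixation probabilities and (conditional) sojourn/fixation times.

    All matrices follow the transient-state ordering of ``space``.  In
    exact mode entries are ``fractions.Fraction`` in object arrays.
    """

    space: StateSpace
    r: Number
    exact: bool
    F: np.ndarray        # t x t unconditional sojourn times
    Phi: np.ndarray      # t x 2 absorption probabilities (ext, fix)
    tau_unc: np.ndarray  # t   unconditional fixation times
    T_cond: np.ndarray   # t x t conditional sojourn times given fixation
    tau_cond: np.ndarray  # t  conditional fixation times

    @property
    def fixation_probability(self) -> np.ndarray:
        return self.Phi[:, 1]


def solve(chain: CanonicalChain) -> AbsorptionResult:
    """Solve the absorbing chain for probabilities and times.

    Float mode uses a single LU factorisation of (I - Q); exact mode a
    rational Gauss-Jordan inverse.  Raises ``LinAlgError`` if (I - Q) is
    singular, which would mean absorption is not certain and the chain is
    malformed.
    """
    t = chain.n_transient
    if chain.exact:
        M = np.empty((t, t), dtype=object)
        for i in range(t):
            for j in range(t):
                M[i, j] = Fraction(int(i == j)) - chain.Q[i, j]
        F = _exact_inverse(M)
        Phi = F @ chain.R
    else:
        M = np.eye(t) - chain.Q
        lu = scipy.linalg.lu_factor(M)
        F = scipy.linalg.lu_solve(lu, np.eye(t))
        if not np.all(np.isfinite(F)):
            raise np.linalg.LinAlgError("singular (I - Q)")
        Phi = F @ chain.R
    tau_unc = F.sum(axis=1)
    phi_fix = Phi[:, 1]
    if any(p <= 0 for p in phi_fix):
        raise np.linalg.LinAlgError(
            "zero fixation probability from a transient state; "
            "chain is malformed (graph disconnected or r <= 0?)")
    T_cond = np.empty((t, t), dtype=object if chain.exact else float)
    for i in range(t):
        for j in range(t):
            T_cond[i, j] = F[i, j] * phi_fix[j] / phi_fix[i]
    tau_cond = T_cond.sum(axis=1)
    return AbsorptionResult(space=chain.space, r=chain.r, exact=chain.exact,
                            F=F, Phi=Phi, tau_unc=tau_unc,
                            T_cond=T_cond, tau_cond=tau_cond)


# ---------------------------------------------------------------------------
# Well-mixed closed forms (oracles for the complete graph)
# ---------------------------------------------------------------------------

def closed_form_fixation_probability(N: int, r, i: int = 1) -> Number:
    """Fixation probability of i mutants in a well-mixed population of N.

        phi_{i,N} = (1 - r^-i) / (1 - r^-N),

    with the removable singularity at neutrality patched as phi = i / N.
    Exact when r is a ``Fraction`` or int, float otherwise.
    """
    if not (N >= 2 and 1 <= i <= N):
        raise ValueError("need N >= 2 and 1 <= i <= N")
    if r <= 0:
        raise ValueError("mutant fitness r must be positive")
    if r == 1:
        return Fraction(i, N) if isinstance(r, (int, Fraction)) else i / N
    if isinstance(r, (int, Fraction)):
        r = Fraction(r)
    return (1 - r ** -i) / (1 - r ** -N)


def closed_form_conditional_time(N: int, r) -> float:
    """Expected conditional fixation time of one mutant, well-mixed case.

    The standard birth-death-chain sum

        tau_1 = sum_{k=1}^{N-1} sum_{l=1}^{k} (phi_l / T_l^+)
                                 prod_{m=l+1}^{k} (T_m^- / T_m^+),

    with T^+/T^- the well-mixed transitions and phi_l the closed-form
    fixation probability from l mutants.  Must agree with the matrix solve
    on the complete graph; that agreement is asserted in the test suite.
    """
    exact = isinstance(r, (int, Fraction))
    up = {}
    gamma = {}
    for m in range(1, N):
        u, d = wellmixed_transitions(N, m, r, exact=exact)
        up[m] = u
        gamma[m] = d / u
    total = Fraction(0) if exact else 0.0
    for k in range(1, N):
        prod = Fraction(1) if exact else 1.0
        # descending l so the gamma product can be grown incrementally
        for l in range(k, 0, -1):
            if l < k:
                prod *= gamma[l + 1]
            phi_l = closed_form_fixation_probability(N, r, l)
            total += phi_l / up[l] * prod
    return total


# ---------------------------------------------------------------------------
# Start averaging and strong-selection limits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StartAveraged:
    """Quantities averaged over a uniformly random initial mutant node."""

    weights: dict[int, Number]      # transient state index -> weight
    fixation_probability: Number
    tau_unc: Number
    tau_cond: Number
    sojourn_cond: np.ndarray        # per transient state, start-averaged
    sojourn_unc: np.ndarray


def start_averaged(result: AbsorptionResult,
                   weighting: str = "uniform") -> StartAveraged:
    """Average over the single-mutant starting states.

    ``uniform`` weights each one-mutant orbit by orbit-size / n — the
    first mutant arises on a uniformly random node.  ``fixation`` weights
    additionally by each start's fixation probability (the distribution of
    starts among runs that fixate), offered for sensitivity analysis of
    conditional quantities.
    """
    space = result.space
    starts = space.single_mutant_indices()
    n = space.graph.n_nodes
    exact = result.exact
    w = {i: (Fraction(space.orbit_size(i), n) if exact
             else space.orbit_size(i) / n) for i in starts}
    if weighting == "fixation":
        tot = sum(w[i] * result.Phi[i, 1] for i in starts)
        w = {i: w[i] * result.Phi[i, 1] / tot for i in starts}
    elif weighting != "uniform":
        raise ValueError("weighting must be 'uniform' or 'fixation'")
    def avg(vec):
        return sum(w[i] * vec[i] for i in starts)
    sojourn_cond = np.array([avg(result.T_cond[:, j])
                             for j in range(space.n_transient)],
                            dtype=object if exact else float)
    sojourn_unc = np.array([avg(result.F[:, j])
                            for j in range(space.n_transient)],
                           dtype=object if exact else float)
    return StartAveraged(
        weights=w,
        fixation_probability=avg(result.Phi[:, 1]),
        tau_unc=avg(result.tau_unc),
        tau_cond=avg(result.tau_cond),
        sojourn_cond=sojourn_cond,
        sojourn_unc=sojourn_unc,
    )


@dataclass(frozen=True)
class LimitResult:
    """Numerical strong-selection limit along an increasing r sequence."""

    value: float
    converged: bool
    r_sequence: tuple[float, ...]
    values: tuple[float, ...]


DEFAULT_R_SEQUENCE = (1e2, 1e3, 1e4, 1e5, 1e6)


def strong_selection_limit(quantity: Callable[[float], float],
                           r_sequence: Sequence[float] = DEFAULT_R_SEQUENCE,
                           tol: float = 1e-4) -> LimitResult:
    """Evaluate ``quantity(r)`` along increasing r and report the limit.

    Convergence means the last successive difference is below ``tol``.
    Sojourn and fixation quantities approach their strong-selection limits
    at rate O(1/r), so with the default sequence ending at r = 10^6 the
    final differences are of order 1e-5; the default ``tol`` allows for
    that rate.  Non-convergence sets the flag rather than raising, since
    slow approaches to the limit are informative too.
    """
    rs = tuple(float(r) for r in r_sequence)
    if list(rs) != sorted(rs):
        raise ValueError("r_sequence must be increasing")
    values = tuple(float(quantity(r)) for r in rs)
    converged = len(values) >= 2 and abs(values[-1] - values[-2]) < tol
    return LimitResult(value=values[-1], converged=converged,
                       r_sequence=rs, values=values)
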
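"""Exact and heuristic solvers for the QPMSI and LPMSI selection indices.

The selection problem: choose exactly ``s`` of ``n`` candidate genotypes
(binary decision vector ``x``) to maximize

    Z = sum_i sum_j y_ji x_i  -  k * x^T G x          (QPMSI)
    Z = sum_i sum_j y_ji x_i                           (LPMSI)

subject to the cardinality constraint ``sum_i x_i = s`` and, for every
constrained trait ``j``, the minimum-gain constraint
``sum_i y_ji x_i >= l_j``.  Here ``y`` are standardized
direction-adjusted trait scores, ``G`` the genomic relationship matrix
and ``k >= 0`` the relatedness-penalty weight (``k = 1`` weights gain
and relatedness equally).

The quadratic objective is reduced to a mixed-integer *linear* program
and solved with HiGHS through :func:`scipy.optimize.milp`.  Two exact
linearizations are provided:

``exact_milp`` (default) — Glover's compact linearization: one
    continuous auxiliary ``w_i`` per genotype stands for
    ``x_i * (G x)_i`` via

        w_i >= (G x)_i - U_i (1 - x_i),   w_i >= L_i x_i,

    where ``U_i``/``L_i`` are the largest/smallest achievable row sums
    over any ``s``-subset.  Because the penalty enters the maximization
    negatively, each ``w_i`` sits on its lower envelope at the optimum,
    which equals ``x_i (G x)_i`` exactly for binary ``x``.

``exact_milp_mccormick`` — the classical pairwise product
    linearization: each ``x_i x_j`` (i < j) becomes ``z_ij`` in [0, 1]
    with ``z_ij <= x_i``, ``z_ij <= x_j``, ``z_ij >= x_i + x_j - 1``
    (both directions kept because ``G`` may carry entries of either
    sign).  Exact but with O(n^2) auxiliaries; kept as a cross-check
    backend.

Diagonal terms enter linearly in both since ``x_i^2 = x_i``.

Infeasibility (no size-``s`` subset meets every gain constraint) is a
legitimate outcome, reported through ``SelectionResult.status`` rather
than an exception, together with a diagnostic naming any trait whose
constraint cannot be met even by that trait's own top-``s`` genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Literal, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .errors import CapExceeded, DimensionError, IDMismatch
from .grm import RelationshipMatrix
from .preprocess import GainThresholds, StandardizedTraits, gain_thresholds

logger = logging.getLogger(__name__)

#: feasibility tolerance for the per-trait gain constraints
CONSTRAINT_TOL = 1e-6
#: tolerance used when comparing objective values for ties
OBJECTIVE_TOL = 1e-9
#: default cap on the number of subsets brute force will enumerate
BRUTE_FORCE_CAP = 2_000_000

Method = Literal["exact_milp", "exact_milp_mccormick", "brute_force", "local_search"]
Status = Literal["optimal", "infeasible", "heuristic", "time_limit"]


@dataclass(frozen=True)
class SelectionSpec:
    """Selection run parameters.

    Parameters
    ----------
    s
        Number of genotypes to select, ``1 <= s <= n``.
    k
        Nonnegative weight on the relatedness penalty ``x^T G x``.
        ``k = 0`` reduces QPMSI to LPMSI.
    R
        Per-trait minimum-gain percents (length ``p0``), all ``>= 0``.
    objective_traits
        Indices of the traits entering the objective; ``None`` means all.
    constraint_traits
        Indices of the traits carrying gain constraints; ``None`` means
        all.  Objective and constraint trait sets may differ.
    """

    s: int
    k: float = 1.0
    R: tuple[float, ...] = ()
    objective_traits: tuple[int, ...] | None = None
    constraint_traits: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.s < 1:
            raise ValueError(f"s={self.s} must be >= 1")
        if self.k < 0:
            raise ValueError(f"k={self.k} must be >= 0")
        object.__setattr__(self, "R", tuple(float(r) for r in self.R))
        if self.objective_traits is not None:
            ot = tuple(int(i) for i in self.objective_traits)
            if not ot:
                raise ValueError("objective_traits must be non-empty when given")
            object.__setattr__(self, "objective_traits", ot)
        if self.constraint_traits is not None:
            object.__setattr__(
                self, "constraint_traits", tuple(int(i) for i in self.constraint_traits)
            )


@dataclass(frozen=True)
class SelectionProblem:
    """A fully assembled selection instance (scores, GRM, spec, thresholds)."""

    y: StandardizedTraits
    G: RelationshipMatrix
    spec: SelectionSpec
    l: GainThresholds

    def __post_init__(self):
        if self.y.genotype_ids != self.G.genotype_ids:
            raise IDMismatch("trait table and relationship matrix id orders differ")
        if self.spec.s > self.y.n:
            raise ValueError(f"s={self.spec.s} exceeds n={self.y.n}")
        for idx in (self.spec.objective_traits, self.spec.constraint_traits):
            if idx is not None and any(i < 0 or i >= self.y.p0 for i in idx):
                raise IndexError(f"trait index out of range for p0={self.y.p0}")
        n_constrained = len(self.constraint_trait_indices)
        if len(self.l.l) != n_constrained:
            raise DimensionError(
                f"{len(self.l.l)} thresholds for {n_constrained} constrained trait(s)"
            )

    @property
    def n(self) -> int:
        return self.y.n

    @property
    def objective_trait_indices(self) -> tuple[int, ...]:
        return self.spec.objective_traits or tuple(range(self.y.p0))

    @property
    def constraint_trait_indices(self) -> tuple[int, ...]:
        if self.spec.constraint_traits is None:
            return tuple(range(self.y.p0))
        return self.spec.constraint_traits

    @property
    def merit(self) -> np.ndarray:
        """Per-genotype merit: row sums of y over the objective traits."""
        return self.y.y[:, list(self.objective_trait_indices)].sum(axis=1)

    @property
    def constraint_matrix(self) -> np.ndarray:
        """``n x c`` matrix of y columns carrying gain constraints."""
        return self.y.y[:, list(self.constraint_trait_indices)]


def build_problem(
    y: StandardizedTraits,
    G: RelationshipMatrix,
    spec: SelectionSpec,
) -> SelectionProblem:
    """Assemble a :class:`SelectionProblem`, deriving ``l_j = R_j s / 100``.

    When ``spec.R`` is empty, all constrained traits get ``R_j = 0``.
    """
    c = len(spec.constraint_traits) if spec.constraint_traits is not None else y.p0
    R = spec.R or (0.0,) * c
    if len(R) != c:
        raise DimensionError(f"{len(R)} R values for {c} constrained trait(s)")
    l = gain_thresholds(R, spec.s, n=y.n)
    return SelectionProblem(y=y, G=G, spec=spec, l=l)


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one solver run.

    ``objective = merit_term - k * penalty_term`` for QPMSI and plain
    ``merit_term`` for LPMSI.  For non-optimal statuses (``infeasible``)
    the numeric fields are NaN and ``x`` is all zeros.
    """

    x: np.ndarray
    selected_ids: tuple[str, ...]
    objective: float
    merit_term: float
    penalty_term: float
    status: Status
    solver: str
    message: str = ""

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.x)

    @property
    def s(self) -> int:
        return int(self.x.sum())


def _evaluate(problem: SelectionProblem, idx: np.ndarray) -> tuple[float, float]:
    """(merit, penalty) of a subset given by sorted index array."""
    merit = float(problem.merit[idx].sum())
    penalty = float(problem.G.G[np.ix_(idx, idx)].sum())
    return merit, penalty


def _feasible(problem: SelectionProblem, idx: np.ndarray) -> bool:
    sums = problem.constraint_matrix[idx].sum(axis=0)
    return bool(np.all(sums >= problem.l.l - CONSTRAINT_TOL))


def _result_from_indices(
    problem: SelectionProblem,
    idx: np.ndarray,
    *,
    quadratic: bool,
    status: Status,
    solver: str,
    message: str = "",
) -> SelectionResult:
    idx = np.sort(np.asarray(idx, dtype=int))
    x = np.zeros(problem.n, dtype=int)
    x[idx] = 1
    merit, penalty = _evaluate(problem, idx)
    objective = merit - problem.spec.k * penalty if quadratic else merit
    return SelectionResult(
        x=x,
        selected_ids=tuple(problem.y.genotype_ids[i] for i in idx),
        objective=objective,
        merit_term=merit,
        penalty_term=penalty,
        status=status,
        solver=solver,
        message=message,
    )


def _infeasible_result(problem: SelectionProblem, solver: str) -> SelectionResult:
    return SelectionResult(
        x=np.zeros(problem.n, dtype=int),
        selected_ids=(),
        objective=float("nan"),
        merit_term=float("nan"),
        penalty_term=float("nan"),
        status="infeasible",
        solver=solver,
        message=infeasibility_diagnostic(problem),
    )


def infeasibility_diagnostic(problem: SelectionProblem) -> str:
    """Explain which gain constraints are individually unsatisfiable.

    For each constrained trait, the largest attainable constraint sum
    under the cardinality constraint alone is the sum of that trait's
    top-``s`` scores; if even that falls short of ``l_j`` the trait is
    unsatisfiable on its own.  Joint infeasibility can also arise from
    conflicts between traits, in which case no single culprit exists.
    """
    s = problem.spec.s
    Yc = problem.constraint_matrix
    bad = []
    for pos, j in enumerate(problem.constraint_trait_indices):
        top = np.sort(Yc[:, pos])[::-1][:s].sum()
        if top < problem.l.l[pos] - CONSTRAINT_TOL:
            bad.append(
                f"{problem.y.trait_names[j]} (best attainable {top:.4g} < l={problem.l.l[pos]:.4g})"
            )
    if bad:
        return "unsatisfiable gain constraint(s) even for the trait's own top-s set: " + "; ".join(bad)
    return ("no size-s subset satisfies all gain constraints jointly; "
            "consider lowering R, lowering k, or falling back to the linear index")


# ---------------------------------------------------------------------------
# exact MILP
# ---------------------------------------------------------------------------

def _milp_constraints_linear(problem: SelectionProblem, n_aux: int):
    """Cardinality + gain constraints on [x, z] variables."""
    n = problem.n
    rows = []
    # sum x = s
    card = sparse.hstack(
        [sparse.csr_matrix(np.ones((1, n))), sparse.csr_matrix((1, n_aux))]
    )
    rows.append(LinearConstraint(card, problem.spec.s, problem.spec.s))
    Yc = problem.constraint_matrix
    if Yc.shape[1]:
        gain = sparse.hstack(
            [sparse.csr_matrix(Yc.T), sparse.csr_matrix((Yc.shape[1], n_aux))]
        )
        rows.append(LinearConstraint(gain, problem.l.l, np.inf))
    return rows


def _subset_row_bounds(G: np.ndarray, s: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional per-row bounds on (G x)_i for the Glover constraints.

    ``U_i`` bounds ``(G x)_i`` from above over subsets *excluding* i
    (the only case where the big-M constraint must go slack), so the
    diagonal entry is left out; ``L_i`` bounds it from below over
    subsets *including* i, so ``G_ii`` plus the ``s - 1`` smallest
    off-diagonal entries.  Conditioning tightens the LP relaxation
    relative to unconditional row bounds.
    """
    n = G.shape[0]
    off = G[~np.eye(n, dtype=bool)].reshape(n, n - 1)
    off_sorted = np.sort(off, axis=1)
    U = off_sorted[:, -s:].sum(axis=1) if s <= n - 1 else off_sorted.sum(axis=1)
    L = np.diag(G) + off_sorted[:, : s - 1].sum(axis=1)
    # box bound on w_i itself: either 0 (x_i = 0) or g_i with i selected
    w_hi = np.maximum(0.0, np.diag(G) + off_sorted[:, n - s :].sum(axis=1))
    return L, U, w_hi


def _solve_exact_milp(
    problem: SelectionProblem, *, quadratic: bool,
    formulation: Literal["glover", "mccormick"] = "glover",
) -> SelectionResult:
    n = problem.n
    s = problem.spec.s
    k = problem.spec.k
    G = problem.G.G
    merit = problem.merit
    quad = quadratic and k > 0

    if not quad:
        c = np.concatenate([-merit])
        constraints = _milp_constraints_linear(problem, 0)
        integrality = np.ones(n)
        bounds = Bounds(np.zeros(n), np.ones(n))
    elif formulation == "glover":
        # w_i stands for x_i * (G x)_i; penalty = sum_i w_i
        L, U, w_hi = _subset_row_bounds(G, s)
        c = np.concatenate([-merit, k * np.ones(n)])
        constraints = _milp_constraints_linear(problem, n)
        # w_i - (G x)_i + U_i x_i >= -infty .. actually >= ... rearranged:
        # w_i >= (Gx)_i - U_i(1 - x_i)  <=>  w_i - (Gx)_i - U_i x_i >= -U_i
        A1 = sparse.hstack([
            sparse.csr_matrix(-G - np.diag(U)), sparse.identity(n, format="csr")
        ])
        constraints.append(LinearConstraint(A1, -U, np.inf))
        # w_i >= L_i x_i
        A2 = sparse.hstack([
            sparse.csr_matrix(-np.diag(L)), sparse.identity(n, format="csr")
        ])
        constraints.append(LinearConstraint(A2, 0.0, np.inf))
        integrality = np.concatenate([np.ones(n), np.zeros(n)])
        lo = np.concatenate([np.zeros(n), np.minimum(L, 0.0)])
        hi = np.concatenate([np.ones(n), w_hi])
        bounds = Bounds(lo, hi)
    else:
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n) if G[i, j] != 0.0]
        n_aux = len(pairs)
        # objective: milp minimizes, we maximize merit - k*(diag + 2*offdiag)
        c_x = -(merit - k * np.diag(G))
        c_z = np.array([2.0 * k * G[i, j] for i, j in pairs])
        c = np.concatenate([c_x, c_z])
        constraints = _milp_constraints_linear(problem, n_aux)
        if n_aux:
            # z_ij <= x_i ; z_ij <= x_j ; z_ij >= x_i + x_j - 1
            data, ri, ci = [], [], []
            for r, (i, j) in enumerate(pairs):
                ri += [2 * r, 2 * r, 2 * r + 1, 2 * r + 1]
                ci += [n + r, i, n + r, j]
                data += [1.0, -1.0, 1.0, -1.0]
            ub_mat = sparse.csr_matrix((data, (ri, ci)), shape=(2 * n_aux, n + n_aux))
            constraints.append(LinearConstraint(ub_mat, -np.inf, 0.0))
            data, ri, ci = [], [], []
            for r, (i, j) in enumerate(pairs):
                ri += [r, r, r]
                ci += [n + r, i, j]
                data += [1.0, -1.0, -1.0]
            lb_mat = sparse.csr_matrix((data, (ri, ci)), shape=(n_aux, n + n_aux))
            constraints.append(LinearConstraint(lb_mat, -1.0, np.inf))
        integrality = np.concatenate([np.ones(n), np.zeros(n_aux)])
        bounds = Bounds(np.zeros(n + n_aux), np.ones(n + n_aux))

    res = milp(c=c, constraints=constraints, integrality=integrality, bounds=bounds)

    solver = "scipy-highs-milp"
    if res.status == 2:  # proven infeasible
        return _infeasible_result(problem, solver)
    if res.status == 1:
        return SelectionResult(
            x=np.zeros(problem.n, dtype=int), selected_ids=(),
            objective=float("nan"), merit_term=float("nan"),
            penalty_term=float("nan"), status="time_limit", solver=solver,
            message=res.message,
        )
    if not res.success:
        raise RuntimeError(f"MILP solver failed: {res.message}")
    idx = np.flatnonzero(np.round(res.x[:n]) > 0.5)
    assert idx.size == problem.spec.s, "cardinality constraint violated by solver"
    return _result_from_indices(
        problem, idx, quadratic=quadratic, status="optimal", solver=solver
    )


# ---------------------------------------------------------------------------
# brute force oracle
# ---------------------------------------------------------------------------

def brute_force_select(
    problem: SelectionProblem,
    objective: Literal["qpmsi", "lpmsi"] = "qpmsi",
    *,
    cap: int = BRUTE_FORCE_CAP,
) -> SelectionResult:
    """Exhaustively enumerate every size-``s`` subset (independent oracle).

    Discards subsets violating any gain constraint and returns the
    feasible maximizer of the requested objective.  Subsets are visited
    in lexicographic index order and a candidate replaces the incumbent
    only when strictly better (beyond ``OBJECTIVE_TOL``), so ties
    resolve to the lexicographically smallest index set.

    Raises
    ------
    CapExceeded
        When ``C(n, s)`` exceeds ``cap``.
    """
    n, s = problem.n, problem.spec.s
    n_subsets = comb(n, s)
    if n_subsets > cap:
        raise CapExceeded(f"C({n},{s}) = {n_subsets} exceeds cap {cap}")
    quadratic = objective == "qpmsi"
    k = problem.spec.k
    merit = problem.merit
    G = problem.G.G
    Yc = problem.constraint_matrix
    l = problem.l.l

    best_idx: tuple[int, ...] | None = None
    best_obj = -np.inf
    for subset in combinations(range(n), s):
        idx = np.array(subset)
        if l.size and not np.all(Yc[idx].sum(axis=0) >= l - CONSTRAINT_TOL):
            continue
        obj = float(merit[idx].sum())
        if quadratic:
            obj -= k * float(G[np.ix_(idx, idx)].sum())
        if obj > best_obj + OBJECTIVE_TOL:
            best_obj, best_idx = obj, subset
    if best_idx is None:
        return _infeasible_result(problem, "brute-force")
    return _result_from_indices(
        problem, np.array(best_idx), quadratic=quadratic,
        status="optimal", solver="brute-force",
    )


# ---------------------------------------------------------------------------
# local search heuristic
# ---------------------------------------------------------------------------

def _local_search(problem: SelectionProblem, *, quadratic: bool, seed: int) -> SelectionResult:
    """Greedy start + steepest single-swap descent.

    Starts from the top-``s`` genotypes by linear merit, repairs
    feasibility by swaps that reduce total constraint violation, then
    improves the objective by the best improving swap until a local
    optimum.  Cannot prove optimality or infeasibility; returns status
    ``heuristic`` (or ``infeasible`` when repair fails, which for this
    method means "none found", not a certificate).
    """
    rng = np.random.default_rng(seed)
    n, s, k = problem.n, problem.spec.s, problem.spec.k
    merit, G = problem.merit, problem.G.G
    Yc, l = problem.constraint_matrix, problem.l.l

    selected = set(np.argsort(-merit, kind="stable")[:s].tolist())

    def violation(sel: set) -> float:
        idx = np.fromiter(sel, dtype=int)
        if not l.size:
            return 0.0
        gap = l - Yc[idx].sum(axis=0)
        return float(np.clip(gap, 0.0, None).sum())

    def objective_of(sel: set) -> float:
        idx = np.fromiter(sel, dtype=int)
        obj = float(merit[idx].sum())
        if quadratic:
            obj -= k * float(G[np.ix_(idx, idx)].sum())
        return obj

    # repair phase
    for _ in range(200):
        v = violation(selected)
        if v <= CONSTRAINT_TOL:
            break
        candidates = [(i, j) for i in selected for j in range(n) if j not in selected]
        rng.shuffle(candidates)
        best_move, best_v = None, v
        for i, j in candidates:
            trial = (selected - {i}) | {j}
            tv = violation(trial)
            if tv < best_v - 1e-12:
                best_move, best_v = (i, j), tv
        if best_move is None:
            return _infeasible_result(problem, "local-search")
        selected = (selected - {best_move[0]}) | {best_move[1]}

    if violation(selected) > CONSTRAINT_TOL:
        return _infeasible_result(problem, "local-search")

    # improvement phase
    improved = True
    while improved:
        improved = False
        cur = objective_of(selected)
        moves = [(i, j) for i in selected for j in range(n) if j not in selected]
        rng.shuffle(moves)
        best_move, best_obj = None, cur
        for i, j in moves:
            trial = (selected - {i}) | {j}
            if violation(trial) > CONSTRAINT_TOL:
                continue
            obj = objective_of(trial)
            if obj > best_obj + OBJECTIVE_TOL:
                best_move, best_obj = (i, j), obj
        if best_move is not None:
            selected = (selected - {best_move[0]}) | {best_move[1]}
            improved = True

    return _result_from_indices(
        problem, np.fromiter(selected, dtype=int), quadratic=quadratic,
        status="heuristic", solver="local-search",
    )


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def solve_qpmsi(
    problem: SelectionProblem,
    method: Method = "exact_milp",
    seed: int = 0,
) -> SelectionResult:
    """Solve the coancestry-penalized quadratic selection index.

    Parameters
    ----------
    problem
        Assembled instance (see :func:`build_problem`).
    method
        ``"exact_milp"`` (default, provably optimal: Glover
        linearization + HiGHS), ``"exact_milp_mccormick"`` (provably
        optimal pairwise linearization, slower), ``"brute_force"``
        (exhaustive oracle, small instances only), or ``"local_search"``
        (swap heuristic).
    seed
        Random seed; only ``local_search`` uses it, exact paths ignore it.
    """
    if method == "exact_milp":
        return _solve_exact_milp(problem, quadratic=True, formulation="glover")
    if method == "exact_milp_mccormick":
        return _solve_exact_milp(problem, quadratic=True, formulation="mccormick")
    if method == "brute_force":
        return brute_force_select(problem, "qpmsi")
    if method == "local_search":
        return _local_search(problem, quadratic=True, seed=seed)
    raise ValueError(f"unknown method {method!r}")


def solve_lpmsi(problem: SelectionProblem, method: Method = "exact_milp") -> SelectionResult:
    """Solve the linear (merit-only) selection index under the same constraints.

    The relatedness weight ``k`` plays no role in the objective; the
    penalty term ``x^T G x`` is still evaluated on the chosen set so the
    relatedness metrics can be reported.  Fast path: the top-``s``
    genotypes by summed merit are unconstrained-optimal, so when that
    set happens to satisfy every gain constraint it is returned without
    invoking the MILP.
    """
    s = problem.spec.s
    top = np.sort(np.argsort(-problem.merit, kind="stable")[:s])
    if _feasible(problem, top):
        return _result_from_indices(
            problem, top, quadratic=False, status="optimal", solver="top-s",
        )
    if method == "brute_force":
        return brute_force_select(problem, "lpmsi")
    return _solve_exact_milp(problem, quadratic=False)
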
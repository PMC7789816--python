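"""Optimal contribution selection (OCS) for conservation breeding.

Given the kinship matrix M of the breeding candidates, OCS chooses a vector
of genetic contributions c (fractions of the next generation's genes, c ≥ 0,
male and female contributions each summing to 0.5) that minimises the
next-generation population mean kinship ``mk̄_min = c' M c``.  On the founder
genome equivalents scale the achievable ceiling is the *potential diversity*
``N_oc = 1/(2·mk̄_min)``.

Two objectives are supported:

* ``min_pkin`` — plain mean kinship minimisation;
* ``min_pkin_at_native`` — minimise the kinship at native alleles, the ratio
  ``(c' fN c)/(c' Q c)``, optionally while keeping the next generation's mean
  kinship below an upper bound and its native contribution above a lower
  bound.  The reciprocal scale value is ``N_ocatN = 1/(2·objective)``.

The optional mean-kinship bound follows the classical rate-of-inbreeding
argument: ``ub_mk = mk̄ + (1 − mk̄)·ΔF`` with ``ΔF = 1/(2·N_e·L)``, where
N_e is the sex-ratio effective size ``4·N_m·N_f/(N_m + N_f)`` and L the
generation interval in years (default 3.2).

Solver: sequential least-squares quadratic programming (SLSQP) with a
deterministic multi-start (uniform sex-balanced point plus seeded random
feasible points) — fractional and constrained problems are prone to poor
single-start convergence.  The fractional objective additionally gets a
Dinkelbach refinement pass, whose fixed point certifies the optimum of the
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .kinship import KinshipMatrix
from .native import NativeKinship


class InfeasibleError(Exception):
    """Raised when the OCS constraint set admits no solution."""


@dataclass(frozen=True)
class ContributionVector:
    ids: tuple[str, ...]
    c: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.c < -1e-9):
            raise ValueError("contributions must be nonnegative")
        if abs(self.c.sum() - 1.0) > 1e-6:
            raise ValueError("contributions must sum to 1")


@dataclass(frozen=True)
class OCSConstraints:
    """Bounds applied to the contribution optimisation.

    ub_mk: upper bound on offspring mean kinship (or None);
    native_lb: lower bound on next-generation native contribution (or None);
    delta_f / n_e / L: the rate-of-inbreeding bookkeeping behind ub_mk.
    """

    ub_mk: Optional[float] = None
    native_lb: Optional[float] = None
    delta_f: Optional[float] = None
    n_e: Optional[float] = None
    L: float = 3.2


@dataclass(frozen=True)
class OCSResult:
    contributions: ContributionVector
    objective_value: float
    potential_fge: float
    converged: bool
    n_iter: int
    kkt_residual: float
    binding: tuple[str, ...] = ()
    message: str = ""


def effective_size(n_male: int, n_female: int) -> float:
    """Sex-ratio effective population size 4·Nm·Nf/(Nm+Nf)."""
    if n_male < 1 or n_female < 1:
        raise ValueError("both sexes must have at least one breeding individual")
    return 4.0 * n_male * n_female / (n_male + n_female)


def kinship_bound(mk_bar: float, n_e: float, L: float = 3.2) -> OCSConstraints:
    """Mean-kinship upper bound from the target rate of inbreeding.

    ΔF = 1/(2·N_e·L); ub_mk = mk̄ + (1 − mk̄)·ΔF.
    """
    if not 0.0 <= mk_bar < 1.0:
        raise ValueError("mk_bar must lie in [0, 1)")
    delta_f = 1.0 / (2.0 * n_e * L)
    return OCSConstraints(
        ub_mk=mk_bar + (1.0 - mk_bar) * delta_f, delta_f=delta_f, n_e=n_e, L=L
    )


# ---------------------------------------------------------------------------
# solver scaffolding
# ---------------------------------------------------------------------------

def _sex_masks(ids: Sequence[str], sexes: dict[str, str]) -> tuple[np.ndarray, np.ndarray]:
    male = np.array([sexes[i] == "male" for i in ids])
    female = np.array([sexes[i] == "female" for i in ids])
    unknown = ~(male | female)
    if unknown.any():
        bad = [i for i, u in zip(ids, unknown) if u]
        raise ValueError(f"unsexed candidates cannot receive contributions: {bad[:5]}")
    if not male.any() or not female.any():
        raise InfeasibleError("both sexes are required for sex-balanced contributions")
    return male, female


def _feasible_starts(
    male: np.ndarray, female: np.ndarray, n_starts: int, seed: int
) -> list[np.ndarray]:
    n = male.size
    starts = []
    c0 = np.zeros(n)
    c0[male] = 0.5 / male.sum()
    c0[female] = 0.5 / female.sum()
    starts.append(c0)
    rng = np.random.default_rng(seed)
    for _ in range(n_starts - 1):
        c = np.zeros(n)
        c[male] = 0.5 * rng.dirichlet(np.ones(male.sum()))
        c[female] = 0.5 * rng.dirichlet(np.ones(female.sum()))
        starts.append(c)
    return starts


def _solve_multistart(fun, jac, constraints, bounds, starts, ftol=1e-10):
    best = None
    for x0 in starts:
        res = minimize(
            fun, x0, jac=jac, method="SLSQP",
            bounds=bounds, constraints=constraints,
            options={"maxiter": 500, "ftol": ftol},
        )
        ok = res.success and _max_violation(res.x, constraints, bounds) < 1e-6
        if best is None or (ok and not best[1]) or (
            ok == best[1] and res.fun < best[0].fun - 1e-14
        ):
            best = (res, ok)
    return best


def _max_violation(x, constraints, bounds) -> float:
    v = max(0.0, float(np.max(-x)), float(np.max(x - 1.0)))
    for con in constraints:
        val = np.atleast_1d(con["fun"](x))
        if con["type"] == "eq":
            v = max(v, float(np.max(np.abs(val))))
        else:
            v = max(v, float(np.max(np.clip(-val, 0.0, None))))
    return v


def _kkt_residual_quadratic(M, x, male, female, active_tol=1e-9):
    """First-order stationarity residual of c'Mc under the sex-sum constraints."""
    g = 2.0 * M @ x
    r = 0.0
    for mask in (male, female):
        gm = g[mask]
        free = x[mask] > active_tol
        if free.any():
            mu = gm[free].mean()
            r = max(r, float(np.max(np.abs(gm[free] - mu))))
            if (~free).any():
                # bound-active coordinates need gradient >= mu
                r = max(r, float(np.max(np.clip(mu - gm[~free], 0.0, None))))
    return r


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

def min_pkin(
    K: KinshipMatrix,
    sexes: dict[str, str],
    constraints: Optional[OCSConstraints] = None,
    n_starts: int = 8,
    seed: int = 0,
) -> OCSResult:
    """Minimise next-generation mean kinship c'Mc (sex-balanced, c ≥ 0).

    With an ``ub_mk`` bound the problem turns into a feasibility check: if
    even the minimum exceeds the bound, :class:`InfeasibleError` is raised
    naming the binding constraint.
    """
    M = K.f
    male, female = _sex_masks(K.ids, sexes)
    cons = [
        {"type": "eq", "fun": lambda c, m=male: c[m].sum() - 0.5,
         "jac": lambda c, m=male: m.astype(float)},
        {"type": "eq", "fun": lambda c, m=female: c[m].sum() - 0.5,
         "jac": lambda c, m=female: m.astype(float)},
    ]
    bounds = [(0.0, 1.0)] * len(K.ids)
    starts = _feasible_starts(male, female, n_starts, seed)
    fun = lambda c: float(c @ M @ c)
    jac = lambda c: 2.0 * (M @ c)
    res, ok = _solve_multistart(fun, jac, cons, bounds, starts)
    mk_min = float(res.fun)
    binding: list[str] = []
    if constraints is not None and constraints.ub_mk is not None:
        if mk_min > constraints.ub_mk + 1e-9:
            raise InfeasibleError(
                f"ub_mk={constraints.ub_mk:.6g} is below the attainable minimum "
                f"mean kinship {mk_min:.6g} (binding constraint: ub_mk)"
            )
        binding.append("ub_mk(slack)")
    kkt = _kkt_residual_quadratic(M, res.x, male, female)
    return OCSResult(
        contributions=ContributionVector(K.ids, np.clip(res.x, 0.0, None)),
        objective_value=mk_min,
        potential_fge=1.0 / (2.0 * mk_min) if mk_min > 0 else np.inf,
        converged=bool(ok),
        n_iter=int(res.nit),
        kkt_residual=kkt,
        binding=tuple(binding),
        message=str(res.message),
    )


def min_pkin_at_native(
    K: KinshipMatrix,
    NK: NativeKinship,
    sexes: dict[str, str],
    constraints: Optional[OCSConstraints] = None,
    n_starts: int = 8,
    seed: int = 0,
    dinkelbach_iters: int = 20,
) -> OCSResult:
    """Minimise the kinship at native alleles (c'·fN·c)/(c'·Q·c).

    Constraints: sex balance, c ≥ 0, optionally ``c'Mc ≤ ub_mk`` and a lower
    bound on the next generation's native contribution ``Σ c_i n_i ≥
    native_lb``.  A Dinkelbach pass refines the direct SLSQP ratio solution:
    at the optimum λ*, ``min c'(fN − λ*Q)c = 0`` over the feasible set.
    """
    if tuple(K.ids) != tuple(NK.ids):
        raise ValueError("kinship and native-kinship matrices cover different members")
    M, FN, Q = K.f, NK.fN, NK.Q
    nvec = NK.native_contribution
    male, female = _sex_masks(K.ids, sexes)
    cons = [
        {"type": "eq", "fun": lambda c, m=male: c[m].sum() - 0.5,
         "jac": lambda c, m=male: m.astype(float)},
        {"type": "eq", "fun": lambda c, m=female: c[m].sum() - 0.5,
         "jac": lambda c, m=female: m.astype(float)},
    ]
    binding: list[str] = []
    if constraints is not None and constraints.ub_mk is not None:
        ub = constraints.ub_mk
        cons.append(
            {"type": "ineq", "fun": lambda c: ub - float(c @ M @ c),
             "jac": lambda c: -2.0 * (M @ c)}
        )
    if constraints is not None and constraints.native_lb is not None:
        lb = constraints.native_lb
        if lb > float(np.max(nvec)) + 1e-12:
            raise InfeasibleError(
                f"native_lb={lb:.6g} exceeds the largest achievable native "
                f"contribution {float(np.max(nvec)):.6g} (binding constraint: native_lb)"
            )
        cons.append(
            {"type": "ineq", "fun": lambda c: float(c @ nvec) - lb,
             "jac": lambda c: nvec}
        )
    bounds = [(0.0, 1.0)] * len(K.ids)
    starts = _feasible_starts(male, female, n_starts, seed)

    eps = 1e-30

    def ratio(c):
        num = float(c @ FN @ c)
        den = float(c @ Q @ c)
        return num / max(den, eps)

    def ratio_jac(c):
        num = float(c @ FN @ c)
        den = max(float(c @ Q @ c), eps)
        return (2.0 * (FN @ c) * den - num * 2.0 * (Q @ c)) / den**2

    best = _solve_multistart(ratio, ratio_jac, cons, bounds, starts)
    res, ok = best
    x = res.x

    # Dinkelbach refinement: parametric subproblems min c'(fN - λQ)c
    lam = ratio(x)
    for _ in range(dinkelbach_iters):
        A = FN - lam * Q
        sub = minimize(
            lambda c: float(c @ A @ c), x, jac=lambda c: 2.0 * (A @ c),
            method="SLSQP", bounds=bounds, constraints=cons,
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if not sub.success:
            break
        new_lam = ratio(sub.x)
        if new_lam <= lam - 1e-14:
            x, lam = sub.x, new_lam
        else:
            break

    obj = ratio(x)
    if constraints is not None:
        if constraints.ub_mk is not None and float(x @ M @ x) > constraints.ub_mk - 1e-9:
            binding.append("ub_mk")
        if constraints.native_lb is not None and float(x @ nvec) < constraints.native_lb + 1e-9:
            binding.append("native_lb")
    # Dinkelbach certificate: residual of min c'(fN - λ*Q)c at the optimum
    A = FN - obj * Q
    kkt = abs(float(x @ A @ x))
    return OCSResult(
        contributions=ContributionVector(K.ids, np.clip(x, 0.0, None)),
        objective_value=obj,
        potential_fge=1.0 / (2.0 * obj) if obj > 0 else np.inf,
        converged=bool(ok),
        n_iter=int(res.nit),
        kkt_residual=kkt,
        binding=tuple(binding),
        message=str(res.message),
    )


def native_lb_default(composition_native: np.ndarray | float, eps: float = 1e-6) -> float:
    """Default native lower bound: current population-average native share.

    The next generation should carry at least as much native ancestry as the
    current population ("strictly greater" enforced as ≥ current + eps).
    """
    cur = float(np.mean(composition_native))
    return min(cur + eps, 1.0)
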
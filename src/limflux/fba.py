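"""Linear inverse model assembly and flux balance analysis.

The constraint system is the linear inverse model

    E x  = f        (steady-state balances and fixed fluxes)
    G x >= h        (irreversibility)
    A x  = b + eps  (approximate equalities: measured fluxes with error sd)

over the flux vector x (mmol/min), with a linear objective optimized by
linear programming.  Flux Variability Analysis reports, per reaction, the
attainable flux range at (or near) the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .errors import InfeasibleProblemError, UnboundedProblemError
from .model import MetabolicModel, stoichiometric_matrix

__all__ = [
    "LinearInverseModel",
    "ObjectiveSpec",
    "FluxVector",
    "build_lim",
    "solve_fba",
    "flux_variability",
    "FEASIBILITY_TOL",
    "FVA_UNIQUENESS_TOL",
]

#: absolute feasibility tolerance for equality/inequality satisfaction
FEASIBILITY_TOL = 1e-9
#: FVA range width (mmol/min) below which a flux counts as uniquely determined
FVA_UNIQUENESS_TOL = 1e-6


@dataclass
class LinearInverseModel:
    """The (E, f, G, h, A, b, sd) constraint system over named reactions."""

    E: np.ndarray
    f: np.ndarray
    G: np.ndarray
    h: np.ndarray
    reaction_labels: list[str]
    A: np.ndarray | None = None
    b: np.ndarray | None = None
    sd: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.reaction_labels)
        self.E = np.atleast_2d(np.asarray(self.E, dtype=float))
        self.f = np.asarray(self.f, dtype=float).ravel()
        self.G = np.atleast_2d(np.asarray(self.G, dtype=float))
        if self.G.size == 0:
            self.G = np.zeros((0, n))
        self.h = np.asarray(self.h, dtype=float).ravel()
        for name, M in (("E", self.E), ("G", self.G)):
            if M.shape[1] != n:
                raise ValueError(f"{name} has {M.shape[1]} columns, expected {n}")
        if self.E.shape[0] != self.f.size:
            raise ValueError("E/f row mismatch")
        if self.G.shape[0] != self.h.size:
            raise ValueError("G/h row mismatch")
        if (self.A is None) != (self.b is None) or (self.A is None) != (self.sd is None):
            raise ValueError("A, b and sd must be provided together")
        if self.A is not None:
            self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
            self.b = np.asarray(self.b, dtype=float).ravel()
            self.sd = np.asarray(self.sd, dtype=float).ravel()
            if self.A.shape != (self.b.size, n):
                raise ValueError("A/b shape mismatch")
            if self.sd.size != self.b.size:
                raise ValueError("sd/b length mismatch")
            if np.any(self.sd <= 0):
                raise ValueError("measurement standard deviations must be > 0")

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_labels)

    def index_of(self, rid: str) -> int:
        try:
            return self.reaction_labels.index(rid)
        except ValueError:
            raise KeyError(rid) from None

    def residuals(self, x: np.ndarray):
        """Return (max |Ex - f|, max violation of Gx >= h)."""
        eq = float(np.max(np.abs(self.E @ x - self.f))) if self.E.size else 0.0
        ineq = float(np.max(self.h - self.G @ x)) if self.G.size else 0.0
        return eq, max(ineq, 0.0)


@dataclass
class ObjectiveSpec:
    """A weighted sum of fluxes to maximize or minimize."""

    coefficients: dict[str, float]
    sense: str = "maximize"

    def __post_init__(self):
        if self.sense not in ("maximize", "minimize"):
            raise ValueError(f"unknown sense {self.sense!r}")

    def dense(self, reaction_labels: list[str]) -> np.ndarray:
        c = np.zeros(len(reaction_labels))
        idx = {rid: j for j, rid in enumerate(reaction_labels)}
        for rid, w in self.coefficients.items():
            if rid not in idx:
                raise KeyError(f"objective reaction {rid!r} not in model")
            c[idx[rid]] = w
        return c

    def value(self, flux: "FluxVector") -> float:
        return sum(w * flux.values[rid] for rid, w in self.coefficients.items())


@dataclass
class FluxVector:
    """Named per-reaction rates in mmol/min."""

    values: dict[str, float]
    objective_value: float | None = None

    @classmethod
    def from_array(cls, x, reaction_labels, objective_value=None):
        return cls(dict(zip(reaction_labels, np.asarray(x, dtype=float))),
                   objective_value=objective_value)

    def to_array(self, reaction_labels) -> np.ndarray:
        return np.array([self.values[rid] for rid in reaction_labels])

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name="flux_mmol_min")

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {"reaction_id": list(self.values), "value": list(self.values.values())}
        )
        if self.objective_value is not None:
            df = pd.concat(
                [df, pd.DataFrame([{"reaction_id": "objective",
                                    "value": self.objective_value}])],
                ignore_index=True,
            )
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def build_lim(
    model: MetabolicModel,
    fixed_fluxes: dict[str, float] | None = None,
    measured_fluxes: dict[str, tuple[float, float]] | None = None,
) -> LinearInverseModel:
    """Assemble the linear inverse model for a metabolic network.

    E stacks the internal-metabolite balance rows (right-hand side 0) with
    one appended unit row per fixed flux; G gets one +1 row (h = 0) per
    irreversible reaction; measured fluxes (value, sd) populate A, b and sd.
    """
    S, _, cols = stoichiometric_matrix(model)
    n = len(cols)
    idx = {rid: j for j, rid in enumerate(cols)}

    E_rows = [S] if S.size else [np.zeros((0, n))]
    f = [np.zeros(S.shape[0])]
    for rid, val in (fixed_fluxes or {}).items():
        if rid not in idx:
            raise KeyError(f"fixed flux on unknown reaction {rid!r}")
        row = np.zeros((1, n))
        row[0, idx[rid]] = 1.0
        E_rows.append(row)
        f.append(np.array([float(val)]))
    E = np.vstack(E_rows)
    f = np.concatenate(f)

    irrev = [j for j, r in enumerate(model.reactions) if not r.reversible]
    G = np.zeros((len(irrev), n))
    for i, j in enumerate(irrev):
        G[i, j] = 1.0
    h = np.zeros(len(irrev))

    A = b = sd = None
    if measured_fluxes:
        A = np.zeros((len(measured_fluxes), n))
        b = np.zeros(len(measured_fluxes))
        sd = np.zeros(len(measured_fluxes))
        for i, (rid, (val, s)) in enumerate(measured_fluxes.items()):
            if rid not in idx:
                raise KeyError(f"measured flux on unknown reaction {rid!r}")
            A[i, idx[rid]] = 1.0
            b[i] = float(val)
            sd[i] = float(s)

    return LinearInverseModel(E=E, f=f, G=G, h=h, reaction_labels=list(cols),
                              A=A, b=b, sd=sd)


# ---------------------------------------------------------------------------
# Linear programming
# ---------------------------------------------------------------------------

def _lp(c, lim: LinearInverseModel, extra_G=None, extra_h=None):
    G, h = lim.G, lim.h
    if extra_G is not None:
        G = np.vstack([G, np.atleast_2d(extra_G)])
        h = np.concatenate([h, np.atleast_1d(extra_h)])
    return linprog(
        c,
        A_eq=lim.E if lim.E.size else None,
        b_eq=lim.f if lim.E.size else None,
        A_ub=-G if G.size else None,
        b_ub=-h if G.size else None,
        bounds=[(None, None)] * lim.n_reactions,
        method="highs",
    )


def _infeasibility_hint(lim: LinearInverseModel):
    """Constraint rows with the largest residual at the least-infeasible point."""
    # least-squares point for the equalities, clipped against inequalities is
    # not needed for a hint: rank the residuals at the LS point.
    x, *_ = np.linalg.lstsq(lim.E, lim.f, rcond=None)
    eq_res = np.abs(lim.E @ x - lim.f)
    ineq_res = np.clip(lim.h - lim.G @ x, 0.0, None) if lim.G.size else np.array([])
    rows = [("E", int(i), float(r)) for i, r in enumerate(eq_res)]
    rows += [("G", int(i), float(r)) for i, r in enumerate(ineq_res)]
    rows.sort(key=lambda t: -t[2])
    return rows[:5]


def _ray_reaction(lim: LinearInverseModel, c) -> str | None:
    """Name a reaction that grows without bound along an improving ray."""
    big = 1e7
    res = linprog(
        c,
        A_eq=lim.E if lim.E.size else None,
        b_eq=lim.f if lim.E.size else None,
        A_ub=-lim.G if lim.G.size else None,
        b_ub=-lim.h if lim.G.size else None,
        bounds=[(-big, big)] * lim.n_reactions,
        method="highs",
    )
    if res.status == 0:
        j = int(np.argmax(np.abs(res.x)))
        if abs(res.x[j]) > 0.5 * big:
            return lim.reaction_labels[j]
    return None


def solve_fba(
    lim: LinearInverseModel,
    objective: ObjectiveSpec,
    feas_tol: float = FEASIBILITY_TOL,
) -> FluxVector:
    """Optimize a linear objective over the constraint polytope by LP.

    Returns the optimizing flux vector with ``objective_value`` set to the
    optimum.  When the optimum is degenerate the solver's deterministic
    choice is returned; use :func:`flux_variability` to detect
    non-uniqueness.
    """
    w = objective.dense(lim.reaction_labels)
    c = -w if objective.sense == "maximize" else w
    res = _lp(c, lim)
    if res.status == 2:
        raise InfeasibleProblemError(
            "FBA constraints are infeasible", conflict_hint=_infeasibility_hint(lim)
        )
    if res.status == 3:
        raise UnboundedProblemError(
            "FBA objective is unbounded", ray_reaction=_ray_reaction(lim, c)
        )
    if res.status != 0:
        raise RuntimeError(f"LP solver failure: {res.message}")
    x = res.x
    eq, ineq = lim.residuals(x)
    if max(eq, ineq) > max(feas_tol, 1e-7):
        raise RuntimeError(f"LP solution violates constraints (eq {eq:g}, ineq {ineq:g})")
    opt = float(w @ x)
    return FluxVector.from_array(x, lim.reaction_labels, objective_value=opt)


def flux_variability(
    lim: LinearInverseModel,
    objective: ObjectiveSpec,
    optimum_fraction: float = 1.0,
) -> dict[str, tuple[float, float]]:
    """Per-reaction (min, max) flux subject to near-optimality.

    The objective is constrained to at least ``optimum_fraction`` times the
    optimum (for maximization; the mirrored bound for minimization), then
    each flux is minimized and maximized in turn.
    """
    if not 0.0 < optimum_fraction <= 1.0:
        raise ValueError("optimum_fraction must be in (0, 1]")
    sol = solve_fba(lim, objective)
    opt = sol.objective_value
    w = objective.dense(lim.reaction_labels)
    if objective.sense == "maximize":
        bound = optimum_fraction * opt if opt >= 0 else opt / optimum_fraction
        extra_G, extra_h = w, bound          # w.x >= bound
    else:
        bound = optimum_fraction * opt if opt <= 0 else opt / optimum_fraction
        extra_G, extra_h = -w, -bound        # w.x <= bound
    out: dict[str, tuple[float, float]] = {}
    n = lim.n_reactions
    for j, rid in enumerate(lim.reaction_labels):
        cj = np.zeros(n)
        cj[j] = 1.0
        lo = _lp(cj, lim, extra_G, extra_h)
        hi = _lp(-cj, lim, extra_G, extra_h)
        vmin = float(lo.fun) if lo.status == 0 else -np.inf
        vmax = float(-hi.fun) if hi.status == 0 else np.inf
        out[rid] = (vmin, vmax)
    return out
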
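"""Lsei-FBA: flux prediction from gene-expression fold changes.

The algorithm scales a reference (healthy) flux distribution by per-reaction
expression fold changes to obtain a rough target, then projects that target
back onto the constraint set by least squares with equalities and
inequalities:

    minimize ||A x - b||^2   subject to   E x = f,  G x >= h

where A selects the reactions with expression data and b holds the
fold-change-scaled reference fluxes.  Steady-state balance and
irreversibility act as hard constraints; exchange rates under the perturbed
condition are outputs of the projection, not inputs.

The constrained least-squares subproblem is solved with a primal active-set
method after null-space elimination of the equalities; when the minimizer is
non-unique in the null directions of A, the minimum-Euclidean-norm
representative is returned.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import linprog

from .errors import InfeasibleProblemError
from .fba import FEASIBILITY_TOL, FluxVector, LinearInverseModel, build_lim
from .model import MetabolicModel, extract_gene_associations, parse_gene_association

__all__ = [
    "FoldChangeTable",
    "LseiProblem",
    "aggregate_fold_changes",
    "rough_estimate",
    "solve_lsei",
    "lsei_fba",
]

_POLICIES = ("average", "minimum", "geometric_mean")


@dataclass
class FoldChangeTable:
    """Per-gene expression fold changes.

    ``entries`` are on the scale given by ``source_scale``; linear fold
    changes must be strictly positive.  The multiplication with reference
    fluxes happens in linear space, so log2 tables are converted with
    ``2 ** value`` first.
    """

    entries: dict[str, float]
    source_scale: str = "linear"

    def __post_init__(self):
        if self.source_scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.source_scale!r}")
        if self.source_scale == "linear" and any(v <= 0 for v in self.entries.values()):
            bad = [g for g, v in self.entries.items() if v <= 0]
            raise ValueError(f"non-positive linear fold changes for genes {bad}")

    def to_linear(self) -> "FoldChangeTable":
        if self.source_scale == "linear":
            return self
        return FoldChangeTable(
            {g: float(2.0 ** v) for g, v in self.entries.items()}, "linear"
        )

    @classmethod
    def from_csv(cls, path, source_scale="linear"):
        import pandas as pd

        df = pd.read_csv(path)
        return cls(dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float))),
                   source_scale=source_scale)


def _aggregate(values: list[float], policy: str) -> float:
    if policy == "average":
        return float(np.mean(values))
    if policy == "minimum":
        return float(np.min(values))
    if policy == "geometric_mean":
        return float(np.exp(np.mean(np.log(values))))
    raise ValueError(f"unknown policy {policy!r}; choose from {_POLICIES}")


def _structured_value(node, fc: dict[str, float]) -> float | None:
    """min over AND-complexes, mean over OR-isoforms; None if no data."""
    if node[0] == "gene":
        return fc.get(node[1])
    vals = [v for v in (_structured_value(ch, fc) for ch in node[1]) if v is not None]
    if not vals:
        return None
    return float(np.min(vals)) if node[0] == "and" else float(np.mean(vals))


def aggregate_fold_changes(
    associations: dict[str, list[str] | str],
    fc: FoldChangeTable,
    policy: str = "average",
    structured: bool = False,
) -> dict[str, float]:
    """Aggregate gene fold changes to one linear fold change per reaction.

    ``associations`` maps reaction ids to either a flat gene list or a
    boolean association string.  Genes absent from the table are skipped
    within a reaction; reactions with no measured gene are omitted.  The
    default flattening policy averages linear fold changes (arithmetic
    mean); ``minimum`` and ``geometric_mean`` are alternatives.  With
    ``structured=True`` the boolean structure is honoured instead:
    minimum over AND-joined complex subunits, mean over OR-joined isoforms.
    """
    fc_lin = fc.to_linear().entries
    out: dict[str, float] = {}
    for rid, assoc in associations.items():
        if structured and isinstance(assoc, str):
            val = _structured_value(parse_gene_association(assoc), fc_lin)
            if val is not None:
                out[rid] = val
            continue
        if isinstance(assoc, str):
            from .model import gene_association_genes

            genes = gene_association_genes(assoc)
        else:
            genes = list(assoc)
        values = [fc_lin[g] for g in genes if g in fc_lin]
        if values:
            out[rid] = _aggregate(values, policy)
    if associations and not out:
        warnings.warn("no reaction has expression data; empty aggregation",
                      stacklevel=2)
    return out


def rough_estimate(
    reference_flux: FluxVector, reaction_fc: dict[str, float]
) -> dict[str, float]:
    """Fold-change-scaled targets: target(r) = reference(r) * fc(r).

    The signed reference value is scaled, so the flux direction is
    preserved: an expression increase on a release flux (negative sign)
    predicts a larger release.
    """
    return {
        rid: reference_flux.values[rid] * f for rid, f in reaction_fc.items()
    }


@dataclass
class LseiProblem:
    """Least-squares problem with equality and inequality constraints.

    A is a 0/1 selector over reactions with expression data; b holds the
    corresponding fold-change-scaled targets (mmol/min).
    """

    E: np.ndarray
    f: np.ndarray
    G: np.ndarray
    h: np.ndarray
    A: np.ndarray
    b: np.ndarray
    reaction_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.E = np.atleast_2d(np.asarray(self.E, dtype=float))
        self.f = np.asarray(self.f, dtype=float).ravel()
        self.G = np.atleast_2d(np.asarray(self.G, dtype=float))
        self.h = np.asarray(self.h, dtype=float).ravel()
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.b = np.asarray(self.b, dtype=float).ravel()
        if self.A.shape[0] != self.b.size:
            raise ValueError("A/b row mismatch")


# ---------------------------------------------------------------------------
# Active-set solver
# ---------------------------------------------------------------------------

_RANK_TOL = 1e-10


def _feasible_point(E, f, G, h):
    n = E.shape[1] if E.size else G.shape[1]
    res = linprog(
        np.zeros(n),
        A_eq=E if E.size else None,
        b_eq=f if E.size else None,
        A_ub=-G if G.size else None,
        b_ub=-h if G.size else None,
        bounds=[(None, None)] * n,
        method="highs",
    )
    if res.status != 0:
        raise InfeasibleProblemError("constraint set {Ex=f, Gx>=h} is empty")
    return res.x


def _eq_constrained_ls(Ar, br, C, d):
    """Minimum-norm argmin ||Ar q - br|| subject to C q = d."""
    if C.size == 0:
        q, *_ = np.linalg.lstsq(Ar, br, rcond=None)
        return q
    qp, *_ = np.linalg.lstsq(C, d, rcond=None)
    Zc = null_space(C, rcond=_RANK_TOL)
    if Zc.size == 0:
        return qp
    u, *_ = np.linalg.lstsq(Ar @ Zc, br - Ar @ qp, rcond=None)
    return qp + Zc @ u


def solve_lsei(problem: LseiProblem, feas_tol: float = FEASIBILITY_TOL) -> FluxVector:
    """Solve min ||Ax-b||^2 s.t. Ex=f, Gx>=h by a primal active-set method.

    Rank deficiency in A or in the constraints is handled throughout via
    minimum-norm least squares; among minimizers that differ only in null
    directions of A, the minimum-Euclidean-norm flux vector is preferred.
    """
    E, f, G, h, A, b = (problem.E, problem.f, problem.G, problem.h,
                        problem.A, problem.b)
    n = A.shape[1]
    x0 = _feasible_point(E, f, G, h)
    Z = null_space(E, rcond=_RANK_TOL) if E.size else np.eye(n)
    if Z.size == 0:
        # equalities determine x completely
        return FluxVector.from_array(
            x0, problem.reaction_labels or [f"x{j}" for j in range(n)],
            objective_value=float(np.sum((A @ x0 - b) ** 2)),
        )

    Ar = A @ Z
    br = b - A @ x0
    Gr = G @ Z if G.size else np.zeros((0, Z.shape[1]))
    hr = h - G @ x0 if G.size else np.zeros(0)

    k = Z.shape[1]
    q = np.zeros(k)
    act_tol = 1e-9
    active = [i for i in range(Gr.shape[0]) if Gr[i] @ q - hr[i] <= act_tol]
    max_iter = 50 * (k + Gr.shape[0] + 1)

    for _ in range(max_iter):
        C = Gr[active] if active else np.zeros((0, k))
        d = hr[active] if active else np.zeros(0)
        q_star = _eq_constrained_ls(Ar, br, C, d)
        step = q_star - q
        if np.linalg.norm(step) <= 1e-11 * max(1.0, np.linalg.norm(q)):
            # check optimality via Lagrange multipliers of active constraints
            grad = 2.0 * Ar.T @ (Ar @ q - br)
            if not active:
                break
            lam, *_ = np.linalg.lstsq(C.T, grad, rcond=None)
            resid = np.linalg.norm(C.T @ lam - grad)
            if resid > 1e-7 * max(1.0, np.linalg.norm(grad)):
                break  # gradient not in active-constraint span: stationary
            j_min = int(np.argmin(lam))
            if lam[j_min] >= -1e-9:
                break
            active.pop(j_min)
            continue
        # ratio test against inactive constraints
        alpha = 1.0
        blocker = None
        for i in range(Gr.shape[0]):
            if i in active:
                continue
            gi_step = Gr[i] @ step
            if gi_step < -1e-13:
                a_i = (hr[i] - Gr[i] @ q) / gi_step
                if a_i < alpha - 1e-14:
                    alpha = max(a_i, 0.0)
                    blocker = i
        q = q + alpha * step
        if blocker is not None:
            active.append(blocker)
        elif alpha >= 1.0:
            # reached the unconstrained-in-working-set minimizer; loop once
            # more to test multipliers
            continue

    # minimum-norm tie-break among minimizers (null directions of A within
    # the active-constraint subspace)
    C = Gr[active] if active else np.zeros((0, k))
    M = np.vstack([Ar, C]) if C.size else Ar
    N = null_space(M, rcond=_RANK_TOL) if M.size else np.eye(k)
    if N.size:
        x_cur = x0 + Z @ q
        t, *_ = np.linalg.lstsq(Z @ N, -x_cur, rcond=None)
        q_cand = q + N @ t
        ok = True
        if Gr.size:
            ok = np.all(Gr @ q_cand - hr >= -1e-9)
        if ok:
            q = q_cand

    x = x0 + Z @ q
    labels = problem.reaction_labels or [f"x{j}" for j in range(n)]
    return FluxVector.from_array(
        x, labels, objective_value=float(np.sum((A @ x - b) ** 2))
    )


# ---------------------------------------------------------------------------
# The Lsei-FBA pipeline
# ---------------------------------------------------------------------------

def lsei_fba(
    model: MetabolicModel,
    reference_flux: FluxVector,
    fc: FoldChangeTable,
    policy: str = "average",
    structured: bool = False,
) -> FluxVector:
    """Predict a perturbed flux distribution from expression fold changes.

    Composes fold-change aggregation, the rough scaled estimate, and the
    constrained least-squares projection.  The constraint system comes from
    :func:`build_lim` with **no** fixed exchange fluxes: exchange rates under
    the perturbed condition are estimated, not imposed.
    """
    associations = extract_gene_associations(model)
    reaction_fc = aggregate_fold_changes(
        {rid: model.reaction(rid).gene_association for rid in associations},
        fc, policy=policy, structured=structured,
    )
    targets = rough_estimate(reference_flux, reaction_fc)

    lim = build_lim(model)
    n = lim.n_reactions
    idx = {rid: j for j, rid in enumerate(lim.reaction_labels)}
    A = np.zeros((len(targets), n))
    b = np.zeros(len(targets))
    for i, (rid, t) in enumerate(targets.items()):
        A[i, idx[rid]] = 1.0
        b[i] = t
    problem = LseiProblem(E=lim.E, f=lim.f, G=lim.G, h=lim.h, A=A, b=b,
                          reaction_labels=lim.reaction_labels)
    return solve_lsei(problem)


def lsei_report(
    model: MetabolicModel,
    reference_flux: FluxVector,
    fc: FoldChangeTable,
    predicted: FluxVector,
    policy: str = "average",
):
    """Per-reaction table: reference, fold change, target, final, deviation."""
    import pandas as pd

    associations = extract_gene_associations(model)
    reaction_fc = aggregate_fold_changes(
        {rid: model.reaction(rid).gene_association for rid in associations},
        fc, policy=policy,
    )
    rows = []
    for rid in model.reaction_ids:
        ref = reference_flux.values[rid]
        fcr = reaction_fc.get(rid, math.nan)
        target = ref * fcr if not math.isnan(fcr) else math.nan
        final = predicted.values[rid]
        rows.append(
            {"reaction_id": rid, "reference": ref, "fold_change": fcr,
             "target": target, "final": final,
             "deviation": final - target if not math.isnan(target) else math.nan}
        )
    return pd.DataFrame(rows)
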
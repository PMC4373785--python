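"""Metropolis-Hastings "mirror" sampling of the feasible flux polytope.

Measured fluxes enter as approximate equalities A x = b + eps with Gaussian
error sd, giving the likelihood

    L(x) = exp( -1/2 * sum_i ((A x - b)_i / sd_i)^2 )

while the hard constraints E x = f and G x >= h always hold.  The chain
moves in the affine subspace of equality-feasible points, parameterized as
x = x0 + Z q with Z an orthonormal null-space basis of E.  Gaussian proposal
steps that leave the inequality polytope are reflected across the violated
constraint hyperplanes until feasible (the mirror move, which keeps the
proposal symmetric), then accepted or rejected by the Metropolis ratio.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.optimize import linprog

from .errors import DiagnosticsError, InfeasibleProblemError
from .fba import FluxVector, LinearInverseModel

__all__ = [
    "SamplerConfig",
    "FluxEnsemble",
    "sample_ensemble",
    "autocorrelation",
    "ensemble_summary",
]

_RANK_TOL = 1e-10
_MAX_REFLECTIONS = 1000


@dataclass(frozen=True)
class SamplerConfig:
    """Chain configuration.

    Defaults follow the study configuration this sampler is built around:
    10^7 burn-in steps, 10^7 sampling steps thinned by 100 (ensemble size
    10^5), relative proposal scale (``jump``) 0.1.  Tests and examples use
    scaled-down chains.
    """

    n_burnin: int = 10_000_000
    n_iter: int = 10_000_000
    thin: int = 100
    jump: float = 0.1
    seed: int = 1868

    def __post_init__(self):
        if self.thin < 1 or self.n_iter < self.thin:
            raise ValueError("need n_iter >= thin >= 1")
        if self.jump <= 0:
            raise ValueError("jump must be > 0")
        if self.n_burnin < 0:
            raise ValueError("n_burnin must be >= 0")


@dataclass
class FluxEnsemble:
    """Kept samples (rows) of feasible flux vectors plus chain metadata."""

    samples: np.ndarray
    reaction_labels: list[str]
    config: SamplerConfig
    acceptance_rate: float

    @property
    def n_kept(self) -> int:
        return self.samples.shape[0]

    def column(self, rid: str) -> np.ndarray:
        return self.samples[:, self.reaction_labels.index(rid)]

    def to_csv(self, path, sidecar_path=None) -> None:
        pd.DataFrame(self.samples, columns=self.reaction_labels).to_csv(
            path, index=False
        )
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(
                    {"config": asdict(self.config),
                     "acceptance_rate": self.acceptance_rate},
                    fh, indent=2,
                )


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _feasible_start(lim: LinearInverseModel):
    n = lim.n_reactions
    res = linprog(
        np.zeros(n),
        A_eq=lim.E if lim.E.size else None,
        b_eq=lim.f if lim.E.size else None,
        A_ub=-lim.G if lim.G.size else None,
        b_ub=-lim.h if lim.G.size else None,
        bounds=[(None, None)] * n,
        method="highs",
    )
    if res.status != 0:
        raise InfeasibleProblemError("no feasible starting point for the chain")
    return res.x


def _range_along(direction, Gr, hr):
    """Feasible extent of the polytope along a direction (None if unbounded)."""
    if not Gr.size:
        return None
    k = Gr.shape[1]
    lo = linprog(direction, A_ub=-Gr, b_ub=-hr, bounds=[(None, None)] * k,
                 method="highs")
    hi = linprog(-direction, A_ub=-Gr, b_ub=-hr, bounds=[(None, None)] * k,
                 method="highs")
    if lo.status == 0 and hi.status == 0 and -hi.fun > lo.fun:
        return float(-hi.fun - lo.fun)
    return None


def _proposal_transform(Gr, hr, Ar, sd, jump):
    """Linear map L such that proposal steps are ``L @ standard_normal(k)``.

    The proposal is shaped by the Gaussian likelihood: along eigendirections
    of the information matrix (A Z / sd)^T (A Z / sd) the step scale is the
    likelihood standard deviation, so strongly correlated measured fluxes
    (narrow likelihood ridges) are traversed efficiently.  Directions the
    likelihood leaves flat use the feasible range of the polytope instead,
    with 1.0 as a last resort for directions unbounded in both senses.
    ``jump`` multiplies every scale (the relative proposal step size).
    """
    k = Ar.shape[1]
    W = Ar / sd[:, None]
    info = W.T @ W
    evals, evecs = np.linalg.eigh(info)
    scale_max = np.sqrt(max(evals.max(), 0.0))
    scales = np.empty(k)
    for i in range(k):
        if evals[i] > (1e-8 * scale_max) ** 2 and evals[i] > 0:
            scales[i] = 1.0 / np.sqrt(evals[i])
        else:
            rng = _range_along(evecs[:, i], Gr, hr)
            scales[i] = rng if rng is not None else 1.0
    return jump * evecs * scales


def _mirror(p, Gr, hr, tol=1e-12):
    """Reflect p across violated hyperplanes until Gr p >= hr; None if the
    bounce cap is exceeded."""
    if not Gr.size:
        return p
    for _ in range(_MAX_REFLECTIONS):
        resid = Gr @ p - hr
        j = int(np.argmin(resid))
        if resid[j] >= -tol:
            return p
        g = Gr[j]
        p = p - (2.0 * resid[j] / (g @ g)) * g
    return None


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

def sample_ensemble(
    lim: LinearInverseModel,
    config: SamplerConfig | None = None,
    initial: FluxVector | None = None,
) -> FluxEnsemble:
    """Sample flux vectors with density proportional to the Gaussian
    likelihood of the measured fluxes, within the hard constraint polytope.

    The chain starts from ``initial`` (typically an FBA solution) or, when
    none is given, from a feasible point found by LP.  Identical
    seed + config + input produce an identical ensemble.
    """
    if lim.A is None:
        raise ValueError("lim must carry measured fluxes (A, b, sd) to sample")
    config = config or SamplerConfig()

    if initial is not None:
        x0 = initial.to_array(lim.reaction_labels)
    else:
        x0 = _feasible_start(lim)
    eq, ineq = lim.residuals(x0)
    if max(eq, ineq) > 1e-6:
        raise InfeasibleProblemError(
            f"starting point violates constraints (eq {eq:g}, ineq {ineq:g})"
        )

    Z = null_space(lim.E, rcond=_RANK_TOL) if lim.E.size else np.eye(lim.n_reactions)
    n_kept = config.n_iter // config.thin

    if Z.size == 0:
        # the equality system determines a unique point
        samples = np.tile(x0, (n_kept, 1))
        return FluxEnsemble(samples, list(lim.reaction_labels), config, 1.0)

    Gr = lim.G @ Z if lim.G.size else np.zeros((0, Z.shape[1]))
    hr = lim.h - lim.G @ x0 if lim.G.size else np.zeros(0)
    Ar = lim.A @ Z
    r0 = lim.A @ x0 - lim.b
    sd = lim.sd

    k = Z.shape[1]
    L = _proposal_transform(Gr, hr, Ar, sd, config.jump)
    rng = np.random.default_rng(config.seed)

    q = np.zeros(k)
    # nudge the start strictly inside if it sits on the boundary
    if Gr.size and np.min(Gr @ q - hr) < 0:
        q = _mirror(q, Gr, hr)
        if q is None:
            raise InfeasibleProblemError("cannot repair infeasible start")

    def loglik(qv):
        r = (Ar @ qv + r0) / sd
        return -0.5 * float(r @ r)

    ll = loglik(q)
    samples = np.empty((n_kept, lim.n_reactions))
    n_acc = 0
    n_acc_burn = 0
    kept = 0
    total = config.n_burnin + config.n_iter
    for step in range(total):
        prop = q + L @ rng.standard_normal(k)
        prop = _mirror(prop, Gr, hr)
        if prop is not None:
            ll_prop = loglik(prop)
            if ll_prop - ll > np.log(rng.uniform()):
                q, ll = prop, ll_prop
                if step < config.n_burnin:
                    n_acc_burn += 1
                else:
                    n_acc += 1
        if step == config.n_burnin - 1 and config.n_burnin > 0 and n_acc_burn == 0:
            raise DiagnosticsError(
                "no proposal accepted during burn-in; try a smaller jump"
            )
        if step >= config.n_burnin and (step - config.n_burnin + 1) % config.thin == 0:
            samples[kept] = x0 + Z @ q
            kept += 1
    samples = samples[:kept]
    rate = n_acc / config.n_iter if config.n_iter else 0.0
    return FluxEnsemble(samples, list(lim.reaction_labels), config, rate)


# ---------------------------------------------------------------------------
# Diagnostics and summaries
# ---------------------------------------------------------------------------

def autocorrelation(ensemble: FluxEnsemble, reaction_id: str, max_lag: int):
    """Normalized autocorrelation function of one flux trace, lags 0..max_lag.

    A constant trace has no defined autocorrelation; it is reported as 1 at
    lag 0 and 0 elsewhere, with a warning.
    """
    x = ensemble.column(reaction_id)
    if max_lag >= x.size:
        raise ValueError("need n_kept > max_lag")
    x = x - x.mean()
    denom = float(x @ x)
    acf = np.zeros(max_lag + 1)
    acf[0] = 1.0
    if denom <= 1e-300:
        warnings.warn(
            f"trace of {reaction_id!r} is constant; autocorrelation undefined",
            stacklevel=2,
        )
        return acf
    for lag in range(1, max_lag + 1):
        acf[lag] = float(x[:-lag] @ x[lag:]) / denom
    return acf


def ensemble_summary(ensemble: FluxEnsemble) -> pd.DataFrame:
    """Per-reaction mean, sd and 2.5/50/97.5% quantiles of the ensemble."""
    if ensemble.n_kept < 2:
        raise ValueError("need at least 2 samples to summarize")
    s = ensemble.samples
    return pd.DataFrame(
        {
            "mean": s.mean(axis=0),
            "sd": s.std(axis=0, ddof=1),
            "q2.5": np.quantile(s, 0.025, axis=0),
            "median": np.quantile(s, 0.5, axis=0),
            "q97.5": np.quantile(s, 0.975, axis=0),
        },
        index=ensemble.reaction_labels,
    )


def plot_histograms(ensemble: FluxEnsemble, reaction_ids, path, bins=40):
    """Histogram grid for selected fluxes, mean and sd printed above each."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rids = list(reaction_ids)
    ncol = min(4, len(rids))
    nrow = (len(rids) + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow),
                             squeeze=False)
    for ax, rid in zip(axes.ravel(), rids):
        col = ensemble.column(rid)
        ax.hist(col, bins=bins, color="steelblue")
        ax.set_title(f"{rid}\nmean {col.mean():.3f}  sd {col.std(ddof=1):.3f}",
                     fontsize=8)
    for ax in axes.ravel()[len(rids):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
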
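"""Uniform flux sampling of the steady-state polytope and flux–target
correlation analysis.

The feasible set of a stoichiometric model is the polytope
``{v : S v = 0, lb <= v <= ub}``. Sampling it uniformly characterises
the network's feasible states without committing to an objective; the
Pearson correlation of each reaction's sampled flux with a designated
target reaction (here fucoxanthin synthesis) then identifies reactions
whose activity is linearly tied to target production, grouped by
pathway (subsystem).

The sampler is an artificially-centered hit-and-run (ACHR) walk run in
the null-space parameterisation ``v = v0 + N z`` (``N`` an orthonormal
basis of ``ker S``), so every iterate satisfies the steady-state
constraint to machine precision by construction; only the box bounds
are handled by the chord search. Directions are drawn through the
running sample centre, which adapts step geometry to elongated
polytopes. Defaults: burn-in 1000 steps, thinning 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.optimize import linprog

from .metnet import MetabolicModel

__all__ = [
    "FluxSampleMatrix",
    "CorrelationReport",
    "feasible_interior_point",
    "sample_fluxes",
    "correlate_with_target",
    "classify_correlations",
]


@dataclass
class FluxSampleMatrix:
    """Sampled steady-state flux vectors.

    ``samples`` is (n_samples x n_reactions); ``residuals`` holds the
    per-sample steady-state residual ``max |S v|``.
    """

    reaction_ids: list[str]
    samples: np.ndarray
    residuals: np.ndarray
    subsystems: dict[str, str] = field(default_factory=dict)
    target_reaction_id: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.reaction_ids)

    def column(self, rxn_id: str) -> np.ndarray:
        return self.samples[:, self.reaction_ids.index(rxn_id)]


@dataclass
class CorrelationReport:
    """Per-reaction Pearson correlation with the target flux.

    ``table`` columns: ``rxn_id, subsystem, r, constant`` and, after
    :func:`classify_correlations`, ``classification``.
    """

    target_reaction_id: str
    table: pd.DataFrame
    threshold: float | None = None

    def subsystem_summary(self) -> pd.DataFrame:
        """Counts of each classification per subsystem."""
        if "classification" not in self.table.columns:
            raise ValueError("classify the report first (classify_correlations)")
        return (
            self.table.groupby(["subsystem", "classification"])
            .size()
            .unstack(fill_value=0)
            .reset_index()
        )


def feasible_interior_point(model: MetabolicModel) -> np.ndarray:
    """A steady-state flux vector with maximal slack from the bounds.

    Solves ``max s`` s.t. ``S v = 0`` and ``lb + s <= v <= ub - s``
    (s capped at half the narrowest bound range, so fixed fluxes do not
    force s = 0 problems). Raises if the polytope is empty.
    """
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    n = len(model.reactions)
    # variables x = (v, s); slack applies only to non-fixed reactions
    free = ub - lb > 0
    cap = 0.5 * (ub[free] - lb[free]).min() if free.any() else 0.0
    A_ub = []
    b_ub = []
    for j in range(n):
        if not free[j]:
            continue
        row = np.zeros(n + 1)
        row[j], row[n] = -1.0, 1.0  # -v_j + s <= -lb_j
        A_ub.append(row.copy())
        b_ub.append(-lb[j])
        row[j] = 1.0  # v_j + s <= ub_j
        A_ub.append(row)
        b_ub.append(ub[j])
    A_eq = np.hstack([S, np.zeros((S.shape[0], 1))])
    c = np.zeros(n + 1)
    c[n] = -1.0
    bounds = [(lb[j], ub[j]) for j in range(n)] + [(0.0, cap if cap > 0 else 0.0)]
    res = linprog(
        c,
        A_ub=np.array(A_ub) if A_ub else None,
        b_ub=np.array(b_ub) if b_ub else None,
        A_eq=A_eq,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
    )
    if not res.success:
        raise ValueError(f"model is infeasible: {res.message}")
    v0 = res.x[:n]
    # refine the steady-state residual with a least-squares projection
    correction, *_ = np.linalg.lstsq(S, S @ v0, rcond=None)
    v0 = np.clip(v0 - correction, lb, ub)
    return v0


def sample_fluxes(
    model: MetabolicModel,
    n_samples: int,
    method: str = "achr",
    seed: int | None = None,
    tol: float = 1e-8,
    burn_in: int = 1000,
    thinning: int = 100,
) -> FluxSampleMatrix:
    """Sample steady-state flux vectors uniformly from the flux polytope.

    Parameters
    ----------
    model
        The stoichiometric model; must be feasible.
    n_samples
        Number of (thinned) samples to return; >= 2.
    method
        Only ``"achr"`` (artificially-centered hit-and-run) is provided.
    seed
        Seed for the random walk.
    tol
        Maximum allowed steady-state residual ``max |S v|`` per sample.
    burn_in, thinning
        Steps discarded before the first sample, and steps between
        retained samples.

    Raises
    ------
    ValueError
        If the model is infeasible or a sample violates the residual or
        bound contracts (with chain diagnostics in the message).
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if method != "achr":
        raise ValueError(f"unknown sampling method {method!r}")
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    v0 = feasible_interior_point(model)
    # restrict the walk to directions that leave fixed-bound reactions
    # untouched: otherwise every chord through a lb == ub coordinate
    # degenerates to a point and the walk cannot move
    fixed = np.flatnonzero(ub - lb == 0)
    A = S if fixed.size == 0 else np.vstack([S, np.eye(len(model.reactions))[fixed]])
    N = null_space(A)
    rng = np.random.default_rng(seed)
    n_dim = N.shape[1]

    if n_dim == 0:
        samples = np.tile(v0, (n_samples, 1))
    else:
        W = N  # v = v0 + W z
        z = np.zeros(n_dim)
        center = z.copy()
        n_seen = 1
        stored: list[np.ndarray] = [z.copy()]
        samples_z = []
        total_steps = burn_in + n_samples * thinning
        for step in range(total_steps):
            # ACHR direction: through the running centre via a random
            # previous iterate; isotropic fallback while degenerate
            zi = stored[rng.integers(len(stored))]
            d = zi - center
            norm = np.linalg.norm(d)
            if norm < 1e-12:
                d = rng.standard_normal(n_dim)
                norm = np.linalg.norm(d)
            d /= norm
            w = W @ d  # direction in v-space
            v = v0 + W @ z
            with np.errstate(divide="ignore", invalid="ignore"):
                lo = (lb - v) / w
                hi = (ub - v) / w
            mask = np.abs(w) > 1e-12
            alpha_min = np.max(np.minimum(lo, hi)[mask], initial=-np.inf)
            alpha_max = np.min(np.maximum(lo, hi)[mask], initial=np.inf)
            if not np.isfinite(alpha_min) or not np.isfinite(alpha_max):
                alpha = 0.0
            elif alpha_max <= alpha_min:
                alpha = 0.0
            else:
                alpha = rng.uniform(alpha_min, alpha_max)
            z = z + alpha * d
            # running centre over all iterates
            n_seen += 1
            center = center + (z - center) / n_seen
            stored.append(z.copy())
            if len(stored) > 500:  # bound the direction pool
                stored.pop(rng.integers(len(stored) - 1))
            if step >= burn_in and (step - burn_in) % thinning == thinning - 1:
                samples_z.append(z.copy())
        samples = v0[None, :] + np.array(samples_z) @ W.T

    residuals = np.max(np.abs(samples @ S.T), axis=1)
    if residuals.max() > tol:
        raise ValueError(
            f"steady-state residual {residuals.max():.3e} exceeds tol {tol:.1e} "
            f"(null-space dim {N.shape[1]}, {n_samples} samples)"
        )
    bound_slack = 10 * np.finfo(float).eps * max(1.0, np.abs(ub).max(), np.abs(lb).max())
    if (samples < lb - bound_slack).any() or (samples > ub + bound_slack).any():
        raise ValueError("sampled flux violates bounds beyond numerical slack")
    samples = np.clip(samples, lb, ub)
    return FluxSampleMatrix(
        reaction_ids=model.reaction_ids,
        samples=samples,
        residuals=residuals,
        subsystems=model.subsystems,
        target_reaction_id=model.target_reaction_id,
    )


def correlate_with_target(
    samples: FluxSampleMatrix,
    target_reaction_id: str | None = None,
    constant_tol: float = 1e-12,
) -> CorrelationReport:
    """Pearson correlation of every reaction's flux with the target flux.

    Reactions whose flux has (numerically) zero variance are reported
    with ``r = 0`` and ``constant = True`` — Pearson r is undefined for
    them; they are classified as uncorrelated downstream. A degenerate
    (zero-variance) *target* raises, suggesting bound relaxation.
    """
    target = target_reaction_id or samples.target_reaction_id
    if target is None:
        raise ValueError("no target reaction specified")
    if target not in samples.reaction_ids:
        raise KeyError(f"target reaction {target!r} not in sample matrix")
    X = samples.samples
    t = samples.column(target)
    scale = np.maximum(1.0, np.abs(X).max(axis=0))
    sds = X.std(axis=0)
    constant = sds <= constant_tol * scale
    t_idx = samples.reaction_ids.index(target)
    if constant[t_idx]:
        raise ValueError(
            f"target reaction {target!r} has zero flux variance in the samples; "
            "the polytope is degenerate along it — consider relaxing bounds"
        )
    tc = t - t.mean()
    t_sd = tc.std()
    rs = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        if constant[j]:
            continue
        xc = X[:, j] - X[:, j].mean()
        rs[j] = float(np.mean(xc * tc) / (xc.std() * t_sd))
    rs[t_idx] = 1.0
    rs = np.clip(rs, -1.0, 1.0)
    table = pd.DataFrame(
        {
            "rxn_id": samples.reaction_ids,
            "subsystem": [samples.subsystems.get(r, "") for r in samples.reaction_ids],
            "r": rs,
            "constant": constant,
        }
    )
    return CorrelationReport(target_reaction_id=target, table=table)


def classify_correlations(report: CorrelationReport, threshold: float = 0.7) -> CorrelationReport:
    """Label each reaction positive / negative / uncorrelated.

    ``positive`` iff ``r >= threshold``, ``negative`` iff
    ``r <= -threshold``, otherwise (and for constant-flux reactions)
    ``uncorrelated``. ``threshold`` in (0, 1]; the raw r column is kept
    so counts can be recomputed at any other threshold.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    table = report.table.copy()
    cls = np.where(
        table["constant"],
        "uncorrelated",
        np.where(
            table["r"] >= threshold,
            "positive",
            np.where(table["r"] <= -threshold, "negative", "uncorrelated"),
        ),
    )
    table["classification"] = cls
    return CorrelationReport(
        target_reaction_id=report.target_reaction_id, table=table, threshold=threshold
    )
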
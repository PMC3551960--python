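"""Presence-only maximum-entropy distribution model.

A minimal, self-contained Gibbs model over grid cells: among all cell
distributions whose feature expectations match the presence sample, take
the one of maximum entropy relative to a uniform background. That
distribution has the form q(i) = exp(sum_j lambda_j f_j(i)) / Z, and the
lambdas are found by maximizing the L1-penalized mean log-likelihood of
the presence cells. Features are standardized linear and quadratic terms
of the environmental variables; hinge/threshold/product features and the
logistic output transform of the Phillips software are deliberately out
of scope — this is a reconstruction of the principle, not of any
particular release.

The optimizer is proximal gradient ascent (soft-threshold step for the L1
term) with backtracking, which makes the penalized objective exactly
non-decreasing across iterations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .grids import EnvStack, GridError, RegionMask, SuitabilityMap
from .occurrences import PresenceGrid

#: Standardized features are clamped to this many sd at prediction time so
#: extrapolated climates cannot overflow the exponential.
CLAMP_SD = 6.0


@dataclass
class MaxentModel:
    species: str
    feature_defs: list[tuple[str, str]]  # (variable, 'linear' | 'quadratic')
    weights: np.ndarray
    feature_means: np.ndarray  # per base variable, over background
    feature_sds: np.ndarray
    variables: list[str]
    log_normalizer: float
    beta: float
    converged: bool = True
    objective_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.feature_defs):
            raise GridError("one weight per feature required")
        if not np.all(np.isfinite(self.feature_means)) or np.any(self.feature_sds <= 0):
            raise GridError("standardization constants must be finite with sd > 0")

    def to_json(self) -> str:
        return json.dumps(
            {
                "species": self.species,
                "feature_defs": self.feature_defs,
                "weights": self.weights.tolist(),
                "feature_means": np.asarray(self.feature_means).tolist(),
                "feature_sds": np.asarray(self.feature_sds).tolist(),
                "variables": self.variables,
                "log_normalizer": self.log_normalizer,
                "beta": self.beta,
                "converged": self.converged,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MaxentModel":
        d = json.loads(text)
        return cls(
            species=d["species"],
            feature_defs=[tuple(fd) for fd in d["feature_defs"]],
            weights=np.array(d["weights"]),
            feature_means=np.array(d["feature_means"]),
            feature_sds=np.array(d["feature_sds"]),
            variables=d["variables"],
            log_normalizer=d["log_normalizer"],
            beta=d["beta"],
            converged=d["converged"],
        )


def default_features(variables: list[str]) -> list[tuple[str, str]]:
    return [(v, t) for v in variables for t in ("linear", "quadratic")]


def _feature_matrix(
    env: EnvStack,
    cells: np.ndarray,
    variables: list[str],
    feature_defs: list[tuple[str, str]],
    means: np.ndarray,
    sds: np.ndarray,
    clamp: bool = False,
) -> np.ndarray:
    """(n_cells, n_features) standardized feature matrix at flat cell indices."""
    var_idx = {v: k for k, v in enumerate(variables)}
    base = np.stack(
        [(env[v].values.ravel()[cells] - means[var_idx[v]]) / sds[var_idx[v]] for v in variables]
    )
    if clamp:
        base = np.clip(base, -CLAMP_SD, CLAMP_SD)
    cols = []
    for var, transform in feature_defs:
        z = base[var_idx[var]]
        cols.append(z if transform == "linear" else z * z)
    return np.stack(cols, axis=1)


def _objective(lam: np.ndarray, F_pres: np.ndarray, F_bg: np.ndarray, beta: float) -> float:
    scores_bg = F_bg @ lam
    m = scores_bg.max()
    logZ = m + np.log(np.exp(scores_bg - m).sum())
    return float((F_pres @ lam).mean() - logZ - beta * np.abs(lam).sum())


def fit_maxent(
    presence: PresenceGrid,
    env: EnvStack,
    background: RegionMask | None = None,
    beta: float = 0.1,
    max_iter: int = 500,
    tol: float = 1e-7,
    feature_defs: list[tuple[str, str]] | None = None,
    variables: list[str] | None = None,
) -> MaxentModel:
    """Fit the Gibbs weights by penalized maximum likelihood over unique cells.

    The objective is mean presence log-likelihood under
    q(i) = exp(lam . f_i)/Z (Z over background cells) minus
    beta * ||lam||_1. The background defaults to all sea cells; it must
    contain every presence cell. Duplicate presence records have no effect
    because fitting is at cell level.
    """
    if variables is None:
        variables = [v for v in sorted(env.layers) if v != "depth"]
    env.require(variables)
    if feature_defs is None:
        feature_defs = default_features(variables)
    spec = env.spec
    bg_mask = env.sea_mask if background is None else (background.member & env.sea_mask)
    bg_cells = np.flatnonzero(bg_mask.ravel())
    if bg_cells.size == 0:
        raise GridError("background contains no usable cells")
    pres_cells = np.flatnonzero((presence.present & bg_mask).ravel())
    if pres_cells.size < 5:
        raise GridError(f"need >= 5 presence cells inside the background, got {pres_cells.size}")

    var_vals = np.stack([env[v].values.ravel()[bg_cells] for v in variables])
    if not np.all(np.isfinite(var_vals)):
        raise GridError("non-finite feature values over background")
    means = var_vals.mean(axis=1)
    sds = var_vals.std(axis=1)
    sds = np.where(sds > 0, sds, 1.0)

    F_bg = _feature_matrix(env, bg_cells, variables, feature_defs, means, sds)
    F_pres = _feature_matrix(env, pres_cells, variables, feature_defs, means, sds)
    mean_pres = F_pres.mean(axis=0)

    lam = np.zeros(len(feature_defs))
    step = 1.0
    obj = _objective(lam, F_pres, F_bg, beta)
    trace = [obj]
    converged = False
    for _ in range(max_iter):
        scores = F_bg @ lam
        m = scores.max()
        w = np.exp(scores - m)
        q = w / w.sum()
        grad = mean_pres - q @ F_bg  # d(mean loglik)/d lam
        improved = False
        s = step
        for _bt in range(60):
            cand = lam + s * grad
            cand = np.sign(cand) * np.maximum(np.abs(cand) - s * beta, 0.0)  # prox of beta*L1
            new_obj = _objective(cand, F_pres, F_bg, beta)
            if new_obj >= obj:
                improved = True
                break
            s *= 0.5
        if not improved:
            converged = True
            break
        lam, step = cand, min(s * 2.0, 1e3)
        trace.append(new_obj)
        if new_obj - obj < tol:
            obj = new_obj
            converged = True
            break
        obj = new_obj

    scores_bg = F_bg @ lam
    m = scores_bg.max()
    logZ = float(m + np.log(np.exp(scores_bg - m).sum()))
    return MaxentModel(
        species=presence.species,
        feature_defs=list(feature_defs),
        weights=lam,
        feature_means=means,
        feature_sds=sds,
        variables=list(variables),
        log_normalizer=logZ,
        beta=beta,
        converged=converged,
        objective_trace=trace,
    )


def predict_maxent(model: MaxentModel, env: EnvStack) -> SuitabilityMap:
    """Raw Gibbs scores with training standardization, rescaled by their max.

    Standardized features are clamped to +/-6 sd so that projection into
    climates beyond the training range stays finite.
    """
    env.require(model.variables)
    spec = env.spec
    sea = env.sea_mask
    cells = np.flatnonzero(sea.ravel())
    F = _feature_matrix(
        env, cells, model.variables, model.feature_defs,
        np.asarray(model.feature_means), np.asarray(model.feature_sds), clamp=True,
    )
    scores = F @ model.weights
    raw = np.exp(scores - scores.max())  # max-rescaled, so top cell = 1
    values = np.full(spec.shape, np.nan).ravel()
    values[cells] = raw
    return SuitabilityMap(
        spec=spec,
        values=values.reshape(spec.shape),
        species=model.species,
        model="maxent",
        period=env.period_label,
    )
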
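"""Gradient-descent weight learning with discrete levels and direct search.

The trainable parameters are the sender promoter strengths (signed weights,
mCherry arb. units).  For a pattern matrix P (patterns x bits) and a target
vector t of High/Low receiver-EYFP levels, the loss is the span-normalized
squared error

    L(w) = 1/2 * sum_j ((sigma(P_j . w) - t_j) / span)^2

where sigma is the receiver activation function and span its output dynamic
range (beta_m).  Continuous training follows the analytic gradient with a
halve-on-overshoot step-size schedule, so the recorded loss trajectory is
non-increasing.  Because in the wet lab only a discrete set of promoter
strengths exists, weights can be constrained to a level palette: either
projected after continuous convergence (default) or after every step, and
then refined by a direct search that exhaustively evaluates palette
combinations in an index neighbourhood of the current solution.  For grids
where the exhaustive neighbourhood is infeasible, training falls back to
iterated greedy coordinate sweeps over the palette (still monotone in loss).

Learning-rate convention: the update is w <- w - eta * K_d^2 * grad, where
K_d is the receiver's dissociation constant on the weighted-sum axis.  The
K_d^2 factor makes eta dimensionless (the normalized gradient has units of
1/weight), so the default eta = 0.1 moves weights by a sensible fraction of
the axis scale regardless of units.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .consortium import ReceiverSpec, receiver_response, receiver_response_derivative
from .patterns import PatternSet, TargetSpec

logger = logging.getLogger("qsperceptron")

__all__ = [
    "DEFAULT_PALETTE",
    "TrainingConfig",
    "TrainingResult",
    "MulticlassResult",
    "default_target_levels",
    "loss",
    "responses",
    "gradient",
    "train",
    "project_discrete",
    "direct_search",
    "coordinate_search",
    "train_multiclass",
]

#: Default discrete weight palette: the calibrated activator sender levels
#: (450, 900, 3500 mCherry a.u. at the 33.3 uM induction dose), 0 for an
#: absent / aTc-suppressed sender, and -735 for the P_lux repressor
#: (alpha_hat_m = -alpha_m).
DEFAULT_PALETTE = (-735.0, 0.0, 450.0, 900.0, 3500.0)


@dataclass
class TrainingConfig:
    """Hyperparameters for weight learning.

    eta: dimensionless learning rate (see module docstring).
    palette: allowed discrete weight levels, or None for continuous mode.
    projection: "post" projects once after continuous convergence (then runs
        the direct search); "every" projects after each accepted step.
    direct_search_radius: neighbourhood half-width in palette-index steps.
    direct_search_budget: maximum neighbourhood size direct_search accepts.
    init_range: weight range for seeded uniform initialization in continuous
        mode (discrete mode initializes within the positive palette range).
    """

    eta: float = 0.1
    max_iter: int = 10_000
    loss_tol: float = 1e-4
    grad_step: float = 1.0
    palette: Optional[Sequence[float]] = None
    projection: str = "post"
    direct_search_radius: int = 1
    direct_search_budget: int = 300_000
    seed: int = 0
    init_policy: str = "uniform"
    init_range: tuple[float, float] = (0.0, 3500.0)
    nonnegative: bool = False
    min_eta_factor: float = 1e-12
    n_restarts: int = 3
    plateau_tol: float = 1e-7

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.palette is not None:
            pal = sorted(float(v) for v in self.palette)
            if not pal:
                raise ValueError("palette must be non-empty in discrete mode")
            self.palette = pal
        if self.projection not in ("post", "every"):
            raise ValueError("projection must be 'post' or 'every'")
        if self.direct_search_radius < 1:
            raise ValueError("direct_search_radius must be >= 1")


@dataclass
class TrainingResult:
    """Learned weights plus the optimization trace."""

    weights: np.ndarray
    loss_trajectory: list[float]
    converged: bool
    diverged: bool
    n_direct_evals: int
    responses: np.ndarray
    targets: np.ndarray
    seed: int
    final_loss: float
    message: str = ""

    def save(self, path) -> None:
        payload = {
            "weights": np.asarray(self.weights).tolist(),
            "loss_trajectory": [float(v) for v in self.loss_trajectory],
            "converged": self.converged,
            "diverged": self.diverged,
            "n_direct_evals": self.n_direct_evals,
            "responses": np.asarray(self.responses).tolist(),
            "targets": np.asarray(self.targets).tolist(),
            "seed": self.seed,
            "final_loss": float(self.final_loss),
            "message": self.message,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def default_target_levels(receiver: Optional[ReceiverSpec] = None) -> tuple[float, float]:
    """(High, Low) target EYFP levels: sigma at 3*K_d input and sigma at 0."""
    receiver = receiver or ReceiverSpec()
    high = float(receiver_response(receiver, 3.0 * receiver.params.K_d))
    low = float(receiver_response(receiver, 0.0))
    return high, low


def _pattern_matrix(patterns) -> np.ndarray:
    if isinstance(patterns, PatternSet):
        return patterns.matrix()
    return np.atleast_2d(np.asarray(patterns, dtype=float))


def responses(w, patterns, receiver: Optional[ReceiverSpec] = None) -> np.ndarray:
    """Simulated receiver EYFP for every pattern under weight vector w."""
    receiver = receiver or ReceiverSpec()
    P = _pattern_matrix(patterns)
    s = P @ np.asarray(w, dtype=float)
    return np.asarray(receiver_response(receiver, s))


def loss(R, t, span: Optional[float] = None, receiver: Optional[ReceiverSpec] = None) -> float:
    """Span-normalized half squared error between responses and targets."""
    R = np.asarray(R, dtype=float)
    t = np.asarray(t, dtype=float)
    if R.shape != t.shape:
        raise ValueError(f"response shape {R.shape} != target shape {t.shape}")
    if span is None:
        span = (receiver or ReceiverSpec()).span
    e = (R - t) / span
    return float(0.5 * np.sum(e * e))


def _loss_of_w(w, P, t, receiver) -> float:
    return loss(responses(w, P, receiver), t, span=receiver.span)


def _loss_many(W, P, t, receiver) -> np.ndarray:
    """Vectorized loss for a stack of candidate weight vectors (K x d)."""
    S = W @ P.T  # K x m
    R = np.asarray(receiver_response(receiver, S))
    E = (R - t[None, :]) / receiver.span
    return 0.5 * np.sum(E * E, axis=1)


def gradient(
    w,
    patterns,
    targets,
    receiver: Optional[ReceiverSpec] = None,
    mode: str = "analytic",
    grad_step: float = 1.0,
) -> np.ndarray:
    """dL/dw via the chain rule through sigma, or central finite differences.

    The analytic form is sum_j (R_j - t_j)/span^2 * sigma'(S_j) * P_ji with
    sigma' the Hill derivative (zero on the clamped branch S_j <= 0).
    """
    receiver = receiver or ReceiverSpec()
    w = np.asarray(w, dtype=float)
    if not np.all(np.isfinite(w)):
        raise FloatingPointError("non-finite weights in gradient evaluation")
    P = _pattern_matrix(patterns)
    t = np.asarray(targets, dtype=float)
    if mode == "analytic":
        s = P @ w
        R = np.asarray(receiver_response(receiver, s))
        dsig = receiver_response_derivative(receiver, s)
        g = P.T @ ((R - t) * dsig) / receiver.span**2
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite gradient")
        return g
    if mode == "fd":
        g = np.zeros_like(w)
        for i in range(len(w)):
            wp, wm = w.copy(), w.copy()
            wp[i] += grad_step
            wm[i] -= grad_step
            g[i] = (_loss_of_w(wp, P, t, receiver) - _loss_of_w(wm, P, t, receiver)) / (
                2.0 * grad_step
            )
        return g
    raise ValueError("mode must be 'analytic' or 'fd'")


# ---------------------------------------------------------------------------
# discrete helpers
# ---------------------------------------------------------------------------

def project_discrete(w, palette: Sequence[float]) -> np.ndarray:
    """Map each weight to the nearest palette level; ties to smaller magnitude."""
    pal = sorted(float(v) for v in palette)
    if not pal:
        raise ValueError("palette must be non-empty")
    pal_arr = np.asarray(pal)
    w = np.atleast_1d(np.asarray(w, dtype=float))
    out = np.empty_like(w)
    for i, wi in enumerate(w):
        dist = np.abs(pal_arr - wi)
        best = dist == dist.min()
        candidates = pal_arr[best]
        # equidistant levels: pick the one of smaller magnitude
        out[i] = candidates[np.argmin(np.abs(candidates))]
    return out


def _palette_indices(w, pal: np.ndarray) -> np.ndarray:
    idx = np.array([int(np.argmin(np.abs(pal - wi))) for wi in np.atleast_1d(w)])
    if not np.allclose(pal[idx], np.atleast_1d(w)):
        raise ValueError("direct search requires weights already on the palette")
    return idx


def direct_search(
    w,
    palette: Sequence[float],
    radius: int,
    patterns,
    targets,
    receiver: Optional[ReceiverSpec] = None,
    budget: int = 300_000,
) -> tuple[np.ndarray, int]:
    """Exhaustive local search over palette combinations around w.

    Evaluates every combination whose palette index differs by at most
    ``radius`` per coordinate and returns the loss-minimizing one (w itself
    if no neighbour improves) together with the number of loss evaluations.
    Never increases the loss.  Refuses neighbourhoods larger than ``budget``
    (use :func:`coordinate_search` for large grids).
    """
    receiver = receiver or ReceiverSpec()
    pal = np.asarray(sorted(float(v) for v in palette))
    P = _pattern_matrix(patterns)
    t = np.asarray(targets, dtype=float)
    w = np.atleast_1d(np.asarray(w, dtype=float))
    idx = _palette_indices(w, pal)
    choices = [
        np.unique(np.clip(np.arange(i - radius, i + radius + 1), 0, len(pal) - 1))
        for i in idx
    ]
    size = int(np.prod([len(c) for c in choices]))
    if size > budget:
        raise ValueError(
            f"direct-search neighbourhood has {size} combinations, exceeding the "
            f"budget of {budget}; reduce the radius or use coordinate_search"
        )
    n_evals = 0
    best_w = w.copy()
    best_loss = _loss_of_w(w, P, t, receiver)
    n_evals += 1
    # chunked vectorized evaluation of the full neighbourhood
    combos = np.array(list(itertools.product(*choices)))
    W = pal[combos]
    for start in range(0, len(W), 8192):
        block = W[start : start + 8192]
        losses = _loss_many(block, P, t, receiver)
        n_evals += len(block)
        k = int(np.argmin(losses))
        if losses[k] < best_loss:
            best_loss = float(losses[k])
            best_w = block[k].copy()
    return best_w, n_evals


def coordinate_search(
    w,
    palette: Sequence[float],
    patterns,
    targets,
    receiver: Optional[ReceiverSpec] = None,
    max_sweeps: int = 50,
) -> tuple[np.ndarray, int]:
    """Greedy coordinate-wise palette search; monotone, for large grids.

    Repeatedly sweeps the coordinates, setting each weight to the palette
    level minimizing the loss with the others fixed, until a full sweep makes
    no change.
    """
    receiver = receiver or ReceiverSpec()
    pal = np.asarray(sorted(float(v) for v in palette))
    P = _pattern_matrix(patterns)
    t = np.asarray(targets, dtype=float)
    w = np.atleast_1d(np.asarray(w, dtype=float)).copy()
    n_evals = 0
    for _ in range(max_sweeps):
        changed = False
        for i in range(len(w)):
            cand = np.tile(w, (len(pal), 1))
            cand[:, i] = pal
            losses = _loss_many(cand, P, t, receiver)
            n_evals += len(pal)
            k = int(np.argmin(losses))
            if pal[k] != w[i] and losses[k] < losses[np.argmin(np.abs(pal - w[i]))] - 1e-15:
                w[i] = pal[k]
                changed = True
        if not changed:
            break
    return w, n_evals


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _init_weights(d: int, cfg: TrainingConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.palette is not None:
        positive = [v for v in cfg.palette if v > 0]
        lo = min(positive) if positive else min(cfg.palette)
        hi = max(cfg.palette)
    else:
        lo, hi = cfg.init_range
    return rng.uniform(lo, hi, size=d)


def train(
    patterns,
    targets,
    cfg: Optional[TrainingConfig] = None,
    receiver: Optional[ReceiverSpec] = None,
    w0: Optional[np.ndarray] = None,
) -> TrainingResult:
    """Learn a weight vector mapping patterns to High/Low target responses.

    Runs ``n_restarts`` independent seeded initializations (gradient descent
    is prone to local minima on this loss surface -- saturated activation and
    the clamp at zero signal both flatten the gradient) and returns the
    lowest-loss result.  Deterministic under a fixed config and seed.
    """
    cfg = cfg or TrainingConfig()
    receiver = receiver or ReceiverSpec()
    best: Optional[TrainingResult] = None
    for r in range(max(cfg.n_restarts, 1)):
        res = _train_once(patterns, targets, cfg, receiver, w0, cfg.seed + 7919 * r)
        if best is None or res.final_loss < best.final_loss:
            best = res
        if w0 is not None:
            break  # explicit start point: restarts would repeat it
    return best


def _train_once(
    patterns,
    targets,
    cfg: TrainingConfig,
    receiver: ReceiverSpec,
    w0: Optional[np.ndarray],
    seed: int,
) -> TrainingResult:
    """One seeded run: gradient descent with halve-on-overshoot (each recorded
    step never increases the loss), then -- in discrete mode with "post"
    projection -- projection onto the palette followed by direct search
    (exhaustive within budget, otherwise greedy coordinate sweeps).  With
    "every" projection, each accepted step is projected immediately."""
    P = _pattern_matrix(patterns)
    t = np.asarray(targets, dtype=float)
    if P.shape[0] != len(t):
        raise ValueError(f"{P.shape[0]} patterns but {len(t)} targets")
    rng = np.random.default_rng(seed)
    w = np.asarray(w0, dtype=float).copy() if w0 is not None else _init_weights(P.shape[1], cfg, rng)
    if cfg.palette is not None and cfg.projection == "every":
        w = project_discrete(w, cfg.palette)

    kd2 = receiver.params.K_d**2
    eta = cfg.eta
    cur = _loss_of_w(w, P, t, receiver)
    trajectory = [cur]
    converged = False
    diverged = False
    message = ""
    n_direct = 0

    for _ in range(cfg.max_iter):
        if cur <= cfg.loss_tol:
            converged = True
            message = "loss below tolerance"
            break
        try:
            g = gradient(w, P, t, receiver)
        except FloatingPointError as exc:
            diverged = True
            message = str(exc)
            break
        gnorm = float(np.linalg.norm(g))
        if gnorm < 1e-14:
            converged = True
            message = "stationary point (zero gradient)"
            break
        # halve-on-overshoot: only accept non-increasing steps
        accepted = False
        while eta >= cfg.eta * cfg.min_eta_factor:
            w_new = w - eta * kd2 * g
            if cfg.nonnegative:
                w_new = np.maximum(w_new, 0.0)
            if cfg.palette is not None and cfg.projection == "every":
                w_new = project_discrete(w_new, cfg.palette)
            new = _loss_of_w(w_new, P, t, receiver)
            if not np.isfinite(new):
                diverged = True
                message = "non-finite loss"
                break
            if new <= cur:
                if np.array_equal(w_new, w):
                    # projected step landed back on the same point
                    eta *= 0.5
                    continue
                w, cur = w_new, new
                trajectory.append(cur)
                eta = min(eta * 1.2, cfg.eta)
                accepted = True
                break
            eta *= 0.5
        if diverged:
            break
        if not accepted:
            converged = True
            message = "step size exhausted (local minimum)"
            break
        if (
            len(trajectory) > 250
            and trajectory[-250] - cur < cfg.plateau_tol * max(trajectory[-250], 1e-30)
        ):
            converged = True
            message = "loss plateau"
            break
    else:
        message = "max_iter reached"

    if cfg.palette is not None and not diverged:
        if cfg.projection == "post":
            w = project_discrete(w, cfg.palette)
            cur = _loss_of_w(w, P, t, receiver)
            trajectory.append(cur)
        # direct-search refinement around the (projected) solution
        pal = np.asarray(cfg.palette)
        span_choices = min(2 * cfg.direct_search_radius + 1, len(pal))
        if span_choices ** P.shape[1] <= cfg.direct_search_budget:
            w, n_direct = direct_search(
                w, cfg.palette, cfg.direct_search_radius, P, t, receiver,
                budget=cfg.direct_search_budget,
            )
        else:
            w, n_direct = coordinate_search(w, cfg.palette, P, t, receiver)
        new = _loss_of_w(w, P, t, receiver)
        if new < cur:
            cur = new
        trajectory.append(cur)

    R = responses(w, P, receiver)
    return TrainingResult(
        weights=np.asarray(w, dtype=float),
        loss_trajectory=trajectory,
        converged=converged and not diverged,
        diverged=diverged,
        n_direct_evals=n_direct,
        responses=R,
        targets=t,
        seed=seed,
        final_loss=float(cur),
        message=message,
    )


@dataclass
class MulticlassResult:
    """Per-category training results and separation margins."""

    results: dict[str, TrainingResult]
    margins: dict[str, float]
    target_spec: TargetSpec

    @property
    def weights(self) -> dict[str, np.ndarray]:
        return {c: r.weights for c, r in self.results.items()}

    def weight_matrix(self) -> np.ndarray:
        return np.stack([r.weights for r in self.results.values()])


def category_margin(R: np.ndarray, own_mask: np.ndarray) -> float:
    """min(own-category response) - max(other-category response)."""
    return float(np.min(R[own_mask]) - np.max(R[~own_mask]))


def train_multiclass(
    pattern_set: PatternSet,
    target_spec: Optional[TargetSpec] = None,
    cfg: Optional[TrainingConfig] = None,
    receiver: Optional[ReceiverSpec] = None,
) -> MulticlassResult:
    """Train one weight vector per category against one-vs-rest H/L targets.

    Categories are trained independently (each from its own seeded
    initialization, derived from the base seed and the category index);
    margins report min(H-response) - max(L-response) per category.
    """
    receiver = receiver or ReceiverSpec()
    cfg = cfg or TrainingConfig()
    if target_spec is None:
        high, low = default_target_levels(receiver)
        target_spec = TargetSpec.one_vs_rest(pattern_set, high, low)
    results: dict[str, TrainingResult] = {}
    margins: dict[str, float] = {}
    for k, c in enumerate(pattern_set.categories):
        sub_cfg = TrainingConfig(
            eta=cfg.eta,
            max_iter=cfg.max_iter,
            loss_tol=cfg.loss_tol,
            grad_step=cfg.grad_step,
            palette=cfg.palette,
            projection=cfg.projection,
            direct_search_radius=cfg.direct_search_radius,
            direct_search_budget=cfg.direct_search_budget,
            seed=cfg.seed + k,
            init_policy=cfg.init_policy,
            init_range=cfg.init_range,
            nonnegative=cfg.nonnegative,
        )
        res = train(pattern_set, target_spec.vectors[c], sub_cfg, receiver)
        results[c] = res
        margins[c] = category_margin(res.responses, pattern_set.category_mask(c))
    return MulticlassResult(results, margins, target_spec)
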
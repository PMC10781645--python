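"""Perceptron template model.

A single readout unit receives 500 inputs whose activities are Gaussian
bumps tiling a sequence template; the template unfolds over one of five
lengths (240, 120, 60, 40, 30 s), tiled periodically across a 120-s
simulation window. Weights are trained with a delta rule toward one of
two targets — a 100-s ramp or an Ornstein-Uhlenbeck process — and the
mean total error over the last 100 of 1000 iterations is reported.

Because the readout is linear, R = W X inherits the period of the input:
a periodic input of period p cannot express a non-periodic 100-s target,
which is why fast inputs fail on the ramp regardless of training. The
closed-form least-squares solution provides the floor any training rule
can reach.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class ModelConfig:
    n_inputs: int = 500
    total_time: float = 120.0        # s, simulation window
    dt: float = 0.03344              # s, simulation step
    n_steps: int = 3588              # floor(total_time / dt)
    sigma_in: float = 7.6            # s, Gaussian input width at template scale
    template_span: float = 240.0     # s, span of the slowest sequence
    sequence_lengths: Sequence[float] = (240.0, 120.0, 60.0, 40.0, 30.0)
    eta: float = 1.0
    momentum: float = 0.95
    n_iterations: int = 1000
    error_tail: int = 100            # iterations averaged for the reported error
    ramp_span: float = 100.0         # s, ramp reaches 1 here
    mu_ou: float = 1.0
    sigma_ou: float = 0.005
    tau_ou: float = 25.6             # s

    def __post_init__(self):
        if self.n_steps <= 0 or self.dt <= 0 or self.n_inputs <= 0:
            raise ValueError("steps, dt and inputs must be positive")
        if abs(self.n_steps * self.dt - self.total_time) > 2 * self.dt:
            raise ValueError("n_steps * dt must approximate total_time")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt


def build_inputs(cfg: ModelConfig, sequence_length: float) -> np.ndarray:
    """Input matrix X (n_inputs x n_steps) for one sequence length.

    The template places ``n_inputs`` Gaussian bumps with equally spaced
    means across ``template_span``; compressing the template to
    ``sequence_length`` scales both the spacing and the widths by
    sequence_length / template_span, and the pattern repeats with period
    ``sequence_length`` over the simulation window.
    """
    if sequence_length <= 0:
        raise ValueError("sequence length must be positive")
    scale = sequence_length / cfg.template_span
    sigma = cfg.sigma_in * scale
    mus = (np.arange(cfg.n_inputs) + 0.5) / cfg.n_inputs * sequence_length
    t = np.mod(cfg.times, sequence_length)
    # wrapped Gaussian on the periodic time axis so every tile is complete
    dt_mat = t[None, :] - mus[:, None]
    dt_mat = dt_mat - sequence_length * np.round(dt_mat / sequence_length)
    return np.exp(-0.5 * (dt_mat / sigma) ** 2)


def make_target(cfg: ModelConfig, kind: str,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Target trace: linear ramp t/100 (clipped at 1) or an OU process.

    The OU process dF/dt = (mu - F)/tau + sigma xi(t) is integrated by
    Euler-Maruyama at the simulation step, starting from the long-term
    mean.
    """
    t = cfg.times
    if kind == "ramp":
        return np.minimum(t / cfg.ramp_span, 1.0)
    if kind != "ou":
        raise ValueError(f"unknown target kind {kind!r}")
    if rng is None:
        rng = np.random.default_rng()
    F = np.empty(cfg.n_steps)
    F[0] = cfg.mu_ou
    noise = rng.standard_normal(cfg.n_steps - 1)
    sq = cfg.sigma_ou * np.sqrt(cfg.dt)
    for i in range(cfg.n_steps - 1):
        F[i + 1] = F[i] + cfg.dt * (cfg.mu_ou - F[i]) / cfg.tau_ou + sq * noise[i]
    return F


def least_squares_error(X: np.ndarray, target: np.ndarray,
                        metric: str = "abs") -> float:
    """Error of the least-squares optimal linear readout.

    ``abs`` returns the total absolute error sum_t |T - R|; ``sse`` the
    summed squared error.
    """
    W, *_ = np.linalg.lstsq(X.T, target, rcond=None)
    resid = target - W @ X
    if metric == "abs":
        return float(np.abs(resid).sum())
    if metric == "sse":
        return float(resid @ resid)
    raise ValueError(f"unknown metric {metric!r}")


def train(X: np.ndarray, target: np.ndarray, cfg: ModelConfig,
          rule: str = "delta") -> dict:
    """Train the readout weights toward the target.

    ``delta`` (default): momentum-accelerated batch delta rule. The update
    direction is the delta-rule gradient X (T - R); the step is normalized
    by the largest eigenvalue of the input Gram matrix X X^T (the standard
    stability condition for a linear readout; an unnormalized step at
    eta = 1 diverges on these strongly overlapping inputs) and a
    heavy-ball momentum term (0.95) accelerates convergence along the
    Gram's small-eigenvalue directions. ``scalar``: the literal
    scalar-error variant dw_i = eta * e * mean_t(x_i) with
    e = sum_t (T - R); kept for comparison, diverges at eta = 1.
    Training aborts with a diagnostic if the error exceeds 1e6.
    """
    n_inputs, n_steps = X.shape
    if target.shape != (n_steps,):
        raise ValueError("target length must match input steps")
    # largest Gram eigenvalue via a few power iterations
    v = np.full(n_inputs, 1.0 / np.sqrt(n_inputs))
    for _ in range(20):
        w = X @ (X.T @ v)
        v = w / np.linalg.norm(w)
    lam_max = float(v @ (X @ (X.T @ v)))
    W = np.zeros(n_inputs)
    mom = np.zeros(n_inputs)
    errors = np.empty(cfg.n_iterations)
    sq_errors = np.empty(cfg.n_iterations)
    for it in range(cfg.n_iterations):
        R = W @ X
        resid = target - R
        errors[it] = np.abs(resid).sum()
        sq_errors[it] = float(resid @ resid)
        if errors[it] > 1e6:
            raise FloatingPointError(
                f"training diverged at iteration {it} (error {errors[it]:.3g})")
        if rule == "delta":
            mom = cfg.momentum * mom + (cfg.eta / lam_max) * (X @ resid)
            W = W + mom
        elif rule == "scalar":
            W = W + cfg.eta * resid.sum() * X.mean(axis=1)
        else:
            raise ValueError(f"unknown rule {rule!r}")
    return {"weights": W, "error_trace": errors,
            "squared_error_trace": sq_errors,
            "mean_total_error": float(errors[-cfg.error_tail:].mean()),
            "mean_squared_error": float(sq_errors[-cfg.error_tail:].mean())}


def evaluate_speed_sweep(cfg: ModelConfig,
                         rng: np.random.Generator | None = None,
                         targets: Sequence[str] = ("ramp", "ou")) -> dict:
    """Train on every sequence length and target; report errors.

    Each condition reports the trained mean total error and the
    least-squares optimum for the same inputs. The OU target is drawn once
    per sweep so all lengths fit the same trace.
    """
    if rng is None:
        rng = np.random.default_rng()
    target_traces = {k: make_target(cfg, k, rng) for k in targets}
    rows = []
    for length in cfg.sequence_lengths:
        X = build_inputs(cfg, length)
        for kind in targets:
            tgt = target_traces[kind]
            res = train(X, tgt, cfg)
            rows.append({
                "sequence_length_s": float(length),
                "target": kind,
                "mean_total_error": res["mean_total_error"],
                "mean_squared_error": res["mean_squared_error"],
                "least_squares_error": least_squares_error(X, tgt),
                "least_squares_sse": least_squares_error(X, tgt, "sse"),
            })
    return {"conditions": rows, "config": cfg}
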
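"""Full-batch optimizers for the auto-encoder and softmax training.

Two routines are provided: Møller's scaled conjugate gradient (SCG), the
default training algorithm of the classifier stack, and a bold-driver
gradient descent as a simpler alternative.  Both operate on a flat parameter
vector and a ``fun(w) -> (cost, grad)`` oracle, and both guarantee a
non-increasing sequence of *accepted* costs: steps that would increase the
cost are rejected and the trust parameter adjusted instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List

import numpy as np

__all__ = ["OptimizeResult", "scg_minimize", "gd_minimize", "minimize"]

CostGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class OptimizeResult:
    """Outcome of a full-batch minimization.

    ``cost_history`` holds the cost of the current iterate after each
    iteration (accepted or rejected), so it is non-increasing.
    """

    x: np.ndarray
    cost: float
    n_iter: int
    cost_history: List[float] = field(default_factory=list)
    converged: bool = False

    @property
    def initial_cost(self) -> float:
        return self.cost_history[0] if self.cost_history else self.cost


def scg_minimize(
    fun: CostGrad,
    x0: np.ndarray,
    max_iter: int = 1000,
    grad_tol: float = 1e-8,
    sigma0: float = 1e-4,
    lambda0: float = 1e-6,
) -> OptimizeResult:
    """Minimize ``fun`` with Møller's scaled conjugate gradient.

    SCG replaces the line search of classical conjugate gradient with a
    Levenberg–Marquardt-style scaling of a one-sided finite-difference
    Hessian-vector product; each iteration costs at most two gradient
    evaluations and a step is taken only when the quadratic-model comparison
    parameter indicates an actual cost reduction.
    """
    w = np.asarray(x0, dtype=float).copy()
    n = w.size
    f_w, grad = fun(w)
    if not np.isfinite(f_w):
        raise FloatingPointError("non-finite cost at the initial point")
    r = -grad
    p = r.copy()
    lam, lam_bar = lambda0, 0.0
    success = True
    delta = 1.0
    history = [float(f_w)]
    converged = False

    k = 0
    while k < max_iter:
        k += 1
        p_sq = float(p @ p)
        if p_sq == 0.0:
            converged = True
            break
        if success:
            # second-order information along p by finite differencing the gradient
            sigma = sigma0 / np.sqrt(p_sq)
            _, grad_plus = fun(w + sigma * p)
            s = (grad_plus - (-r)) / sigma
            delta = float(p @ s)
        # scale the model to make it positive definite
        delta += (lam - lam_bar) * p_sq
        if delta <= 0:
            lam_bar = 2.0 * (lam - delta / p_sq)
            delta = -delta + lam * p_sq
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        w_new = w + alpha * p
        f_new, grad_new = fun(w_new)
        comparison = 2.0 * delta * (f_w - f_new) / mu**2 if mu != 0 else -1.0
        if comparison >= 0 and np.isfinite(f_new):
            # accept the step
            w, f_w = w_new, f_new
            r_new = -grad_new
            lam_bar = 0.0
            success = True
            if k % n == 0:
                p = r_new.copy()  # periodic restart along steepest descent
            else:
                beta = float(r_new @ r_new - r_new @ r) / mu
                p = r_new + beta * p
            r = r_new
            if comparison >= 0.75:
                lam = max(lam * 0.25, 1e-15)
        else:
            lam_bar = lam
            success = False
        if comparison < 0.25:
            lam += delta * (1.0 - comparison) / p_sq
            lam = min(lam, 1e15)
        history.append(float(f_w))
        if float(r @ r) <= grad_tol**2:
            converged = True
            break
        if not np.isfinite(f_w):
            raise FloatingPointError(f"cost diverged at iteration {k}")

    return OptimizeResult(x=w, cost=float(f_w), n_iter=k, cost_history=history, converged=converged)


def gd_minimize(
    fun: CostGrad,
    x0: np.ndarray,
    max_iter: int = 1000,
    lr: float = 0.1,
    grad_tol: float = 1e-8,
) -> OptimizeResult:
    """Bold-driver gradient descent: grow the step on success, halve and
    reject on failure.  Accepted costs are strictly non-increasing."""
    w = np.asarray(x0, dtype=float).copy()
    f_w, grad = fun(w)
    history = [float(f_w)]
    converged = False
    k = 0
    while k < max_iter:
        k += 1
        w_new = w - lr * grad
        f_new, grad_new = fun(w_new)
        if np.isfinite(f_new) and f_new <= f_w:
            w, f_w, grad = w_new, f_new, grad_new
            lr *= 1.05
        else:
            lr *= 0.5
            if lr < 1e-15:
                break
        history.append(float(f_w))
        if float(grad @ grad) <= grad_tol**2:
            converged = True
            break
    if not np.isfinite(f_w):
        raise FloatingPointError(f"cost diverged at iteration {k}")
    return OptimizeResult(x=w, cost=float(f_w), n_iter=k, cost_history=history, converged=converged)


def minimize(fun: CostGrad, x0: np.ndarray, method: str = "scg", **kwargs) -> OptimizeResult:
    """Dispatch to :func:`scg_minimize` (``"scg"``) or :func:`gd_minimize` (``"gd"``)."""
    if method == "scg":
        return scg_minimize(fun, x0, **kwargs)
    if method == "gd":
        return gd_minimize(fun, x0, **kwargs)
    raise ValueError(f"unknown optimizer {method!r}; expected 'scg' or 'gd'")
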
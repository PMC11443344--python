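"""Dung-beetle optimizer (DBO): box-constrained population metaheuristic.

The population is split into four behavioral roles updated each iteration:

* **Rollers** follow a celestial-cue straight-line roll,
  ``x(t+1) = x(t) + alpha*k*x(t-1) + b*dx`` with ``dx = |x(t) - Xw|``, where
  ``Xw`` is the worst position of the current population, ``k`` a deflection
  coefficient, ``b`` a fixed gain and ``alpha`` a per-update random sign.
* **Brood balls** are confined to a spawning region around the current
  population best ``X*``: ``Lb* = max(X*(1-R), Lb)``, ``Ub* = min(X*(1+R), Ub)``
  with ``R = 1 - t/Tmax``; the update is
  ``B(t+1) = X* + b1*(B(t) - Lb*) + b2*(B(t) - Ub*)`` with b1, b2 ~ U(0,1)^D,
  clipped to the spawning region.
* **Foragers** feed around the best-so-far ``Xb`` inside
  ``Lbb = max(Xb(1-R), Lb)``, ``Ubb = min(Xb(1+R), Ub)``:
  ``x(t+1) = x(t) + C1*(x - Lbb) + C2*(x - Ubb)`` with C1 ~ N(0,1) scalar and
  C2 ~ U(0,1)^D, clipped to the global box.
* **Thieves** jump to a Gaussian perturbation of the best-so-far scaled by
  their distance to both incumbents,
  ``x(t+1) = Xb + S*g*(|x - X*| + |x - Xb|)`` with g ~ N(0,1)^D and S = 0.5.
  This stage supplies most of the late-run exploitation; without it the
  three remaining roles stall an order of magnitude short on smooth
  objectives.

A shrinking region is the coordinate box spanned between ``anchor*(1-R)`` and
``anchor*(1+R)`` intersected with the global box (span by min/max per
coordinate, so negative coordinates behave symmetrically); if an anchor
coordinate lies outside the box the region collapses there to the clipped
anchor.  Positions are hard-clipped after every update, fitness ties keep the
earlier incumbent, and the best-so-far history is monotone non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DBOConfig", "DBOResult", "roll_update", "brood_update",
           "forage_update", "thief_update", "optimize"]


@dataclass(frozen=True)
class DBOConfig:
    """Run settings: population, iterations, role split, gains and the box.

    ``role_fractions`` are (rollers, brood balls, foragers, thieves) and must
    sum to 1; a 3-tuple is accepted and means no thieves.
    """

    bounds: tuple                       # ((lb, ub), ...) per dimension
    pop_size: int = 20
    max_iter: int = 8
    k: float = 0.1                      # roller deflection coefficient, (0, 0.2]
    b_roll: float = 0.3                 # roller gain, (0, 1)
    role_fractions: tuple = (0.3, 0.3, 0.25, 0.15)
    s_thief: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4")
        if not 0 < self.k <= 0.2:
            raise ValueError("k must lie in (0, 0.2]")
        if not 0 < self.b_roll < 1:
            raise ValueError("b_roll must lie in (0, 1)")
        fr = self.fractions
        if len(fr) != 4 or min(fr) < 0 or abs(sum(fr) - 1) > 1e-9:
            raise ValueError("role fractions must be nonnegative and sum to 1")
        lb, ub = self.box
        if not np.all(lb < ub):
            raise ValueError("each lower bound must be below its upper bound")

    @property
    def fractions(self) -> tuple:
        fr = tuple(self.role_fractions)
        return fr + (0.0,) if len(fr) == 3 else fr

    @property
    def box(self) -> tuple[np.ndarray, np.ndarray]:
        arr = np.asarray(self.bounds, dtype=float)
        return arr[:, 0], arr[:, 1]


@dataclass
class DBOResult:
    """Best-ever position/fitness and the per-iteration best-so-far history."""

    x_best: np.ndarray
    f_best: float
    history: list[float] = field(default_factory=list)


def _clip(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return np.minimum(np.maximum(x, lo), hi)


def _region(anchor: np.ndarray, r: float, lb: np.ndarray,
            ub: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shrinking region spanned between anchor*(1-R) and anchor*(1+R).

    The span is taken coordinatewise by min/max (well-defined for negative
    coordinates) and intersected with the box; where the intersection is empty
    the region collapses to the clipped anchor.
    """
    a, b = anchor * (1.0 - r), anchor * (1.0 + r)
    lo = np.maximum(np.minimum(a, b), lb)
    hi = np.minimum(np.maximum(a, b), ub)
    bad = lo > hi
    if np.any(bad):
        ref = _clip(anchor, lb, ub)
        lo = np.where(bad, ref, lo)
        hi = np.where(bad, ref, hi)
    return lo, hi


def roll_update(x_t, x_prev, x_worst, k: float, b_roll: float, alpha: float,
                bounds) -> np.ndarray:
    """Straight-line roll toward/away from the worst position, clipped to the box."""
    lb, ub = np.asarray(bounds, dtype=float).T
    dx = np.abs(np.asarray(x_t, float) - np.asarray(x_worst, float))
    new = np.asarray(x_t, float) + alpha * k * np.asarray(x_prev, float) + b_roll * dx
    return _clip(new, lb, ub)


def brood_update(b_t, x_best_local, r: float, bounds, b1=None, b2=None,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Brood-ball move inside the spawning region around the local best.

    ``b1``/``b2`` may be supplied explicitly (deterministic tests); otherwise
    they are drawn U(0,1)^D from ``rng``.
    """
    if not 0 <= r <= 1:
        raise ValueError("R must lie in [0,1]")
    lb, ub = np.asarray(bounds, dtype=float).T
    x_star = np.asarray(x_best_local, dtype=float)
    lo, hi = _region(x_star, r, lb, ub)
    d = x_star.size
    rng = rng or np.random.default_rng()
    b1 = rng.uniform(size=d) if b1 is None else np.asarray(b1, float)
    b2 = rng.uniform(size=d) if b2 is None else np.asarray(b2, float)
    new = x_star + b1 * (np.asarray(b_t, float) - lo) + b2 * (np.asarray(b_t, float) - hi)
    return _clip(new, lo, hi)


def forage_update(x_t, x_best_global, r: float, bounds, c1=None, c2=None,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Forager move around the global best's feeding region, clipped to the box."""
    if not 0 <= r <= 1:
        raise ValueError("R must lie in [0,1]")
    lb, ub = np.asarray(bounds, dtype=float).T
    xb = np.asarray(x_best_global, dtype=float)
    lo, hi = _region(xb, r, lb, ub)
    rng = rng or np.random.default_rng()
    c1 = float(rng.normal()) if c1 is None else float(c1)
    c2 = rng.uniform(size=xb.size) if c2 is None else np.asarray(c2, float)
    x = np.asarray(x_t, dtype=float)
    new = x + c1 * (x - lo) + c2 * (x - hi)
    return _clip(new, lb, ub)


def thief_update(x_t, x_best_local, x_best_global, s: float, bounds,
                 g=None, rng: np.random.Generator | None = None) -> np.ndarray:
    """Thief jump near the global best, scaled by distance to both incumbents."""
    lb, ub = np.asarray(bounds, dtype=float).T
    x = np.asarray(x_t, dtype=float)
    xb = np.asarray(x_best_global, dtype=float)
    x_star = np.asarray(x_best_local, dtype=float)
    rng = rng or np.random.default_rng()
    g = rng.normal(size=x.size) if g is None else np.asarray(g, float)
    new = xb + s * g * (np.abs(x - x_star) + np.abs(x - xb))
    return _clip(new, lb, ub)


def optimize(objective, config: DBOConfig) -> DBOResult:
    """Minimize ``objective`` over the box with the four-role DBO scheme.

    The population is initialized uniformly in the box; each iteration the
    rollers, brood balls, foragers and thieves update their subpopulations,
    everyone is re-evaluated, and the incumbent best/worst bookkeeping is
    refreshed.  Returns the best-ever position plus a best-so-far history of
    length ``max_iter``.
    """
    rng = np.random.default_rng(config.seed)
    lb, ub = config.box
    d = lb.size
    n = config.pop_size
    fr = config.fractions
    n_roll = min(int(round(fr[0] * n)), n)
    n_brood = min(int(round(fr[1] * n)), n - n_roll)
    n_forage = min(int(round(fr[2] * n)), n - n_roll - n_brood)
    rollers = np.arange(n_roll)
    brood = np.arange(n_roll, n_roll + n_brood)
    foragers = np.arange(n_roll + n_brood, n_roll + n_brood + n_forage)
    thieves = np.arange(n_roll + n_brood + n_forage, n)

    def evaluate(x):
        f = float(objective(x))
        if not np.isfinite(f):
            raise ValueError(f"objective returned non-finite value at {x}")
        return f

    pos = rng.uniform(lb, ub, size=(n, d))
    prev = pos.copy()
    fit = np.array([evaluate(x) for x in pos])

    i_best = int(np.argmin(fit))
    x_best, f_best = pos[i_best].copy(), float(fit[i_best])
    history: list[float] = []

    tmax = config.max_iter
    for t in range(1, tmax + 1):
        r = 1.0 - t / tmax
        x_star = pos[int(np.argmin(fit))].copy()      # current population best
        x_worst = pos[int(np.argmax(fit))].copy()     # current population worst
        new = pos.copy()
        for i in rollers:
            alpha = 1.0 if rng.random() < 0.5 else -1.0
            new[i] = roll_update(pos[i], prev[i], x_worst, config.k,
                                 config.b_roll, alpha, config.bounds)
        for i in brood:
            new[i] = brood_update(pos[i], x_star, r, config.bounds, rng=rng)
        for i in foragers:
            new[i] = forage_update(pos[i], x_best, r, config.bounds, rng=rng)
        for i in thieves:
            new[i] = thief_update(pos[i], x_star, x_best, config.s_thief,
                                  config.bounds, rng=rng)
        prev = pos
        pos = new
        fit = np.array([evaluate(x) for x in pos])
        i_best = int(np.argmin(fit))
        if fit[i_best] < f_best:                      # ties keep the incumbent
            x_best, f_best = pos[i_best].copy(), float(fit[i_best])
        history.append(f_best)

    return DBOResult(x_best=x_best, f_best=f_best, history=history)
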
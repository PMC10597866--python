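"""Fish Migration Optimization and its enhanced variant (EFMO).

FMO is a population metaheuristic modeled on the grayling life cycle.  Each
fish carries a position, an energy budget (initially 2), and an age stage in
{0..4}.  Stage counts follow the ratio 1 : 1 : 1 : 0.66 : 0.66 and per-stage
survival rates are (1, 0.93, 0.91, 0.37, 0.66).  One iteration applies

* an energy step — migrating fish (stage >= 2) lose the normalized fitness
  share f_j / Σf; fish that improved their personal best regain
  r1 · E_init;
* a fecundity step — per-stage Bernoulli survival, dead fish replaced by
  newborns (population size is conserved), survivors contract toward the
  global best: Z ← gb + r2 · (Z − gb);
* a motion step — stages 2–3 move with a momentum term
  orispeed = ±(Z − Z_prev) scaled by an energy-dependent consumption, plus
  an attraction E_init · r4 · (gb − Z); stages 0, 1, 4 use the fecundity
  contraction rule.

The *enhanced* variant (EFMO) adds opposition-based learning at
initialization — 30% of the initial fish are replaced by the better of
(candidate, lo + hi − candidate) — and sources the per-fish random draws
r1..r6 from chaotic sine streams r ← (γ/4)·sin(π r) with γ = 4 instead of a
uniform RNG.

The module also provides the four shifted/rotated benchmark functions used
to validate the optimizer (high-conditioned elliptic, bent cigar, discus,
Rosenbrock with offsets 100/200/300/400) and a multi-run comparison harness.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

#: stage-count ratio and per-stage survival rates of the grayling life cycle
STAGE_RATIO = np.array([1.0, 1.0, 1.0, 0.66, 0.66])
SURVIVAL_RATE = np.array([1.0, 0.93, 0.91, 0.37, 0.66])
ENERGY_INIT = 2.0
SINE_GAMMA = 4.0


# -- search space ------------------------------------------------------------

@dataclass
class SearchSpace:
    """Box-constrained minimization problem."""

    lower: np.ndarray
    upper: np.ndarray
    objective: Callable[[np.ndarray], float]

    def __post_init__(self):
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape:
            raise ValueError("bound shapes differ")
        if np.any(self.lower >= self.upper):
            raise ValueError("need lower < upper in every dimension")

    @property
    def dim(self) -> int:
        return self.lower.size

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def evaluate(self, positions: np.ndarray) -> np.ndarray:
        return np.array([float(self.objective(p)) for p in np.atleast_2d(positions)])


# -- chaotic sine map --------------------------------------------------------

def sine_map_next(r: float, gamma: float = SINE_GAMMA) -> float:
    """One step of the sine chaos map r' = (γ/4)·sin(π r); maps [0,1]→[0,1]."""
    return (gamma / 4.0) * float(np.sin(np.pi * r))


class ChaoticStream:
    """Chaotic pseudo-random stream in [0, 1] driven by the sine map."""

    def __init__(self, r0: float, gamma: float = SINE_GAMMA):
        if not (0.0 <= r0 <= 1.0):
            raise ValueError("r0 must lie in [0, 1]")
        self.r = float(r0)
        self.gamma = gamma

    def next(self) -> float:
        self.r = sine_map_next(self.r, self.gamma)
        return self.r


def obl_opposite(x: np.ndarray, space: SearchSpace) -> np.ndarray:
    """Opposition-based-learning reflection lo + hi − x (an involution)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < space.lower - 1e-12) or np.any(x > space.upper + 1e-12):
        raise ValueError("point outside bounds")
    return space.lower + space.upper - x


def stage_assignment(n: int, ratio: np.ndarray = STAGE_RATIO) -> np.ndarray:
    """Stage counts proportional to the life-cycle ratio, summing to n.

    Largest-remainder rounding preserves the total.
    """
    quota = ratio / ratio.sum() * n
    counts = np.floor(quota).astype(int)
    rem = quota - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    stages = np.repeat(np.arange(len(ratio)), counts)
    return stages


# -- motion-rule primitives (kept pure so they can be oracle-checked) --------

def orispeed(z: np.ndarray, z_prev: np.ndarray, r3: float) -> np.ndarray:
    """Directional momentum: Z − Z_prev when r3 >= 0.5, else the reverse."""
    return z - z_prev if r3 >= 0.5 else z_prev - z


def consumption(energy: float, r4: float, r6: float,
                e_init: float = ENERGY_INIT) -> float:
    """Kinetic-energy factor: E_init·r4 while energy lasts, else energy·r6."""
    return e_init * r4 if energy >= e_init else energy * r6


def migration_move(z, z_prev, energy, gb, r3, r4, r6,
                   e_init: float = ENERGY_INIT) -> np.ndarray:
    """Stage-2/3 position update: momentum plus attraction toward the
    global best, applied as an increment (a fish at the global best with no
    momentum stays put)."""
    speed = orispeed(z, z_prev, r3)
    cons = consumption(energy, r4, r6, e_init)
    return z + speed * cons + e_init * r4 * (gb - z)


def reposition(z: np.ndarray, gb: np.ndarray, r: float) -> np.ndarray:
    """Stage-0/1/4 (and fecundity-survivor) contraction toward global best."""
    return gb + r * (z - gb)


# -- optimizer ---------------------------------------------------------------

@dataclass
class FMOResult:
    best_position: np.ndarray
    best_value: float
    history: np.ndarray  # best-so-far per iteration, non-increasing
    n_evaluations: int = 0


class FishMigration:
    """One optimizer run; exposes the life-cycle steps for testing.

    ``use_obl`` / ``use_chaos`` off reproduces the plain FMO; both on is the
    enhanced variant.  ``alpha`` (the published exploration coefficient) is
    kept as a configuration knob but newborn fish are fresh uniform
    individuals, as at initialization.
    """

    def __init__(self, space: SearchSpace, n_fish: int = 70, seed: int = 0,
                 use_obl: bool = True, use_chaos: bool = True,
                 alpha: float = 0.15, max_iter: int = 200):
        if n_fish < 5:
            raise ValueError("need at least one fish per age stage")
        self.space = space
        self.n = n_fish
        self.rng = np.random.default_rng(seed)
        self.use_obl = use_obl
        self.use_chaos = use_chaos
        self.alpha = alpha
        self.max_iter = max_iter
        self.age_every = max(1, int(np.ceil(max_iter / 5)))
        self.n_evaluations = 0

        # auxiliary stream for the enhancements, spawned off the main
        # stream without advancing it: the main draw sequence is then
        # identical with the enhancements on or off (common random numbers,
        # so ablation comparisons are paired)
        self.aux = self.rng.spawn(1)[0]

        lo, hi, d = space.lower, space.upper, space.dim
        pos = lo + self.rng.random((n_fish, d)) * (hi - lo)
        if use_obl:
            k = int(round(0.3 * n_fish))
            idx = self.aux.choice(n_fish, size=k, replace=False)
            opp = lo + hi - pos[idx]
            f_orig = self._eval(pos[idx])
            f_opp = self._eval(opp)
            pos[idx] = np.where((f_opp < f_orig)[:, None], opp, pos[idx])
        self.pos = pos
        self.prev = pos.copy()
        self.energy = np.full(n_fish, ENERGY_INIT)
        self.stage = stage_assignment(n_fish)
        self.fit = self._eval(pos)
        self.pbest = self.fit.copy()
        self.improved = np.zeros(n_fish, dtype=bool)
        b = int(np.argmin(self.fit))
        self.gb_pos = pos[b].copy()
        self.gb_val = float(self.fit[b])
        self.history = [self.gb_val]
        self.iteration = 0
        if use_chaos:
            # one chaotic stream per fish per draw role r1..r6, so draws
            # within an iteration are not deterministic functions of each
            # other
            self.chaos = self.aux.uniform(0.05, 0.95, size=(n_fish, 6))
            self.chaos_dim = self.aux.uniform(0.05, 0.95, size=space.dim)
        else:
            self.chaos = None
        self.stall = 0          # iterations since the global best improved
        self.stall_limit = 5    # chaotic reseeding kicks in past this

    def _eval(self, positions: np.ndarray) -> np.ndarray:
        vals = self.space.evaluate(positions)
        self.n_evaluations += len(vals)
        return vals

    def _draw(self, role: int, chaotic: bool = False) -> np.ndarray:
        """One random number per fish for draw role r1..r6 (0-indexed).

        The enhanced variant substitutes chaotic sine-stream values for the
        perturbation-side draws (r1, r3, r6); the uniform draw is still
        consumed so the main stream stays aligned across variants.  The
        contraction/attraction coefficients (r2, r4, r5) stay uniform
        because the edge-peaked chaotic iterate distribution distorts the
        contraction schedule.
        """
        u = self.rng.random(self.n)
        if chaotic and self.chaos is not None:
            self.chaos[:, role] = (SINE_GAMMA / 4.0) * np.sin(
                np.pi * self.chaos[:, role])
            return self.chaos[:, role].copy()
        return u

    # -- life-cycle steps ----------------------------------------------------

    def energy_step(self) -> None:
        total = self.fit.sum()
        migrating = self.stage >= 2
        if total != 0:
            self.energy[migrating] -= (self.fit / total)[migrating]
        r1 = self._draw(0, chaotic=True)
        self.energy[self.improved] += r1[self.improved] * ENERGY_INIT
        np.maximum(self.energy, 0.0, out=self.energy)

    def fecundity_step(self) -> None:
        # survival is a Bernoulli realization of the population-expectation
        # rule, not one of the update draws r1..r6 — always uniform
        u = self.rng.random(self.n)
        dead = u > SURVIVAL_RATE[self.stage]
        survivors = ~dead
        r2 = self._draw(1)
        self.pos[survivors] = self.gb_pos + r2[survivors, None] * (
            self.pos[survivors] - self.gb_pos)
        n_dead = int(dead.sum())
        if n_dead:
            # newborns are fresh random individuals, as at initialization
            lo, hi = self.space.lower, self.space.upper
            newborn = lo + self.rng.random((n_dead, self.space.dim)) * (hi - lo)
            if self.chaos is not None and self.stall >= self.stall_limit:
                # stagnation: place newborns by chaotic sampling over the
                # whole box to escape the incumbent's basin
                rows = []
                for _ in range(n_dead):
                    self.chaos_dim = (SINE_GAMMA / 4.0) * np.sin(
                        np.pi * self.chaos_dim)
                    rows.append(self.chaos_dim.copy())
                newborn = self.space.lower + np.array(rows) * (
                    self.space.upper - self.space.lower)
            if self.use_obl:
                # opposition applies to every randomly generated candidate:
                # newborns keep the better of (candidate, opposite)
                opp = self.space.lower + self.space.upper - newborn
                f_new = self._eval(newborn)
                f_opp = self._eval(opp)
                newborn = np.where((f_opp < f_new)[:, None], opp, newborn)
            self.pos[dead] = newborn
            self.prev[dead] = self.pos[dead]
            self.stage[dead] = 0
            self.energy[dead] = ENERGY_INIT
            self.pbest[dead] = np.inf
        # spawned-out oldest fish restart the cycle as newborns in place
        spawned = self.stage == 4
        self.stage[spawned] = 0
        self.energy[spawned] = ENERGY_INIT
        self.pos = self.space.clip(self.pos)

    def motion_step(self) -> None:
        r3 = self._draw(2)
        r4 = self._draw(3)
        r6 = self._draw(5)
        sign = np.where(r3 >= 0.5, 1.0, -1.0)
        speed = sign[:, None] * (self.pos - self.prev)
        cons = np.where(self.energy >= ENERGY_INIT,
                        ENERGY_INIT * r4, self.energy * r6)
        move = self.pos + speed * cons[:, None] + ENERGY_INIT * r4[:, None] * (
            self.gb_pos - self.pos)
        r5 = self._draw(4)
        contract = self.gb_pos + r5[:, None] * (self.pos - self.gb_pos)
        migrating = (self.stage == 2) | (self.stage == 3)
        new_pos = np.where(migrating[:, None], move, contract)
        self.prev = self.pos.copy()
        self.pos = self.space.clip(new_pos)

    def step(self) -> float:
        """One full iteration; returns the best-so-far value."""
        self.iteration += 1
        self.energy_step()
        self.fecundity_step()
        self.motion_step()
        if self.iteration % self.age_every == 0:
            np.minimum(self.stage + 1, 4, out=self.stage)
        self.fit = self._eval(self.pos)
        self.improved = self.fit < self.pbest
        np.minimum(self.pbest, self.fit, out=self.pbest)
        b = int(np.argmin(self.fit))
        if self.fit[b] < self.gb_val:
            self.gb_val = float(self.fit[b])
            self.gb_pos = self.pos[b].copy()
            self.stall = 0
        else:
            self.stall += 1
        self.history.append(self.gb_val)
        return self.gb_val

    def run(self) -> FMOResult:
        for _ in range(self.max_iter):
            self.step()
        return FMOResult(self.gb_pos.copy(), self.gb_val,
                         np.asarray(self.history), self.n_evaluations)


def optimize(space: SearchSpace, n_fish: int = 70, max_iter: int = 200,
             seed: int = 0, use_obl: bool = True, use_chaos: bool = True,
             alpha: float = 0.15) -> FMOResult:
    """Run (E)FMO on ``space`` and return the best solution found.

    Defaults (70 fish, 200 iterations) are the method's standard
    validation setting.
    """
    fmo = FishMigration(space, n_fish=n_fish, seed=seed, use_obl=use_obl,
                        use_chaos=use_chaos, alpha=alpha, max_iter=max_iter)
    return fmo.run()


def random_search(space: SearchSpace, n_evals: int, seed: int = 0) -> FMOResult:
    """Uniform random search baseline at a fixed evaluation budget."""
    rng = np.random.default_rng(seed)
    lo, hi = space.lower, space.upper
    pos = lo + rng.random((n_evals, space.dim)) * (hi - lo)
    vals = space.evaluate(pos)
    hist = np.minimum.accumulate(vals)
    b = int(np.argmin(vals))
    return FMOResult(pos[b].copy(), float(vals[b]), hist, n_evals)


# -- benchmark functions -----------------------------------------------------

def elliptic(z: np.ndarray) -> float:
    """High-conditioned elliptic: Σ (10^6)^((i-1)/(d-1)) z_i^2."""
    z = np.asarray(z, dtype=float)
    d = z.size
    expo = np.zeros(d) if d == 1 else np.arange(d) / (d - 1)
    return float(np.sum(1e6 ** expo * z**2))


def bent_cigar(z: np.ndarray) -> float:
    z = np.asarray(z, dtype=float)
    return float(z[0] ** 2 + 1e6 * np.sum(z[1:] ** 2))


def discus(z: np.ndarray) -> float:
    z = np.asarray(z, dtype=float)
    return float(1e6 * z[0] ** 2 + np.sum(z[1:] ** 2))


def rosenbrock(z: np.ndarray) -> float:
    z = np.asarray(z, dtype=float)
    return float(np.sum(100.0 * (z[:-1] ** 2 - z[1:]) ** 2 + (z[:-1] - 1.0) ** 2))


_BASE_FUNCTIONS = {1: elliptic, 2: bent_cigar, 3: discus, 4: rosenbrock}


def random_rotation(dim: int, rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random orthogonal matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((dim, dim)))
    return q * np.sign(np.diag(r))


@dataclass
class BenchmarkFunction:
    """Shifted/rotated test function F(x) = f(M(x − o)) + F*.

    The Rosenbrock form (id 4) maps the inner argument onto the all-ones
    optimum: F4(x) = f4(M · 2.048(x − o)/100 + 1) + F4*.
    """

    which: int
    rotation: np.ndarray
    shift: np.ndarray
    offset: float
    lower: np.ndarray
    upper: np.ndarray

    def __call__(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if self.which == 4:
            z = self.rotation @ (2.048 * (x - self.shift) / 100.0) + 1.0
        else:
            z = self.rotation @ (x - self.shift)
        return _BASE_FUNCTIONS[self.which](z) + self.offset

    def space(self) -> SearchSpace:
        return SearchSpace(self.lower, self.upper, self)


def benchmark(dim: int, which: int, seed: int = 0,
              bounds: tuple[float, float] = (-100.0, 100.0),
              shift_margin: float = 0.8) -> BenchmarkFunction:
    """Build benchmark F1..F4 with a seeded rotation and in-bounds shift."""
    if which not in _BASE_FUNCTIONS:
        raise ValueError("benchmark id must be in {1, 2, 3, 4}")
    rng = np.random.default_rng(seed)
    lo = np.full(dim, bounds[0])
    hi = np.full(dim, bounds[1])
    M = random_rotation(dim, rng)
    center = (lo + hi) / 2.0
    half = (hi - lo) / 2.0
    o = center + rng.uniform(-shift_margin, shift_margin, size=dim) * half
    return BenchmarkFunction(which, M, o, 100.0 * which, lo, hi)


# -- comparison harness ------------------------------------------------------

def comparison_harness(
    functions: dict[str, BenchmarkFunction],
    optimizers: dict[str, Callable[[SearchSpace, int], FMOResult]],
    runs: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Independent seeded runs; Max/Min/Mean/STD (+ wall time) per cell.

    ``optimizers`` maps a name to ``fn(space, seed) -> FMOResult``.  Per-run
    seeds are derived deterministically from ``seed``.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    rows = []
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31, size=runs)
    for fname, func in functions.items():
        space = func.space()
        for oname, opt in optimizers.items():
            vals = []
            t0 = time.perf_counter()
            for s in run_seeds:
                vals.append(opt(space, int(s)).best_value)
            elapsed = time.perf_counter() - t0
            vals = np.asarray(vals)
            rows.append({
                "function": fname, "optimizer": oname,
                "Max": vals.max(), "Min": vals.min(),
                "Mean": vals.mean(), "STD": vals.std(ddof=0),
                "Time": elapsed, "runs": runs,
            })
    return pd.DataFrame(rows)
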
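"""Monte Carlo simulator for pseudopod-based cell movement.

An amoeboid cell is modelled as extending one pseudopod per step.  Each
pseudopod is either a *split* of the current pseudopod (extended at angle
``phi`` to its right or left, with the right/left choice alternating with
probability ``a``) or a *de novo* pseudopod extended in a uniformly
random direction.  The emitted direction additionally carries von Mises
angular noise with SD ``sigma_phi``.  Five parameters fully specify a
strain/condition:

``lambda_p``  pseudopod size (µm)
``s``         fraction of splitting pseudopodia
``a``         right/left alternation bias of consecutive splits
``phi``       splitting angle (degrees)
``sigma_phi`` SD of the extension angle (degrees)

Sign convention (fixed package-wide): left = counter-clockwise = positive
angular increment, right = clockwise = negative.  The first pseudopod of
every trajectory points in a uniformly random direction; a split whose
predecessor was de novo picks its side by a fair coin.

Each simulated step consumes four uniform random numbers (split-or-not,
alternate-or-not, side-after-de-novo, de novo direction) plus one von
Mises draw, so trajectories are reproducible given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Tuple

import numpy as np

from .circular import kappa_from_sigma, normalize_angle

__all__ = [
    "PseudopodParams",
    "PseudopodEvent",
    "Trajectory",
    "next_pseudopod_angle",
    "simulate_trajectory",
    "simulate_ensemble",
]

SIDE_LEFT = "L"
SIDE_RIGHT = "R"
SIDE_NONE = "none"

# synthetic clock used when exporting event tables: one pseudopod every
# 30 s of which ~13 s is the growth phase (step-indexed time only
# rescales the MSD time axis and is otherwise ignored)
DEFAULT_STEP_INTERVAL_S = 30.0
DEFAULT_GROWTH_TIME_S = 13.0


@dataclass(frozen=True)
class PseudopodParams:
    """The five-parameter model of one strain/condition."""

    lambda_p: float
    s: float
    a: float
    phi: float
    sigma_phi: float

    def __post_init__(self):
        if not self.lambda_p > 0:
            raise ValueError(f"lambda_p must be > 0, got {self.lambda_p}")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"s must be in [0, 1], got {self.s}")
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"a must be in [0, 1], got {self.a}")
        if not 0.0 <= self.phi <= 180.0:
            raise ValueError(f"phi must be in [0, 180] degrees, got {self.phi}")
        if not self.sigma_phi >= 0.0:
            raise ValueError(f"sigma_phi must be >= 0, got {self.sigma_phi}")

    @property
    def kappa(self) -> float:
        """von Mises concentration of the angular noise (inf for sigma=0)."""
        return kappa_from_sigma(self.sigma_phi)


@dataclass(frozen=True)
class PseudopodEvent:
    """One extension event: a vector from start to end of pseudopod growth."""

    index: int
    kind: str  # "split" | "de_novo"
    side: str  # "R" | "L" | "none"
    alpha: float  # absolute direction of extension, degrees
    x_start: float
    y_start: float
    x_end: float
    y_end: float
    t_start: Optional[float] = None
    t_end: Optional[float] = None


@dataclass(frozen=True)
class Trajectory:
    """Ordered tip positions, starting at the origin."""

    positions: np.ndarray  # shape (n_steps + 1, 2)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 2:
            raise ValueError("positions must have shape (n_steps + 1, 2)")
        if not np.allclose(pos[0], 0.0):
            raise ValueError("trajectories start at the origin")
        object.__setattr__(self, "positions", pos)

    @property
    def n_steps(self) -> int:
        return self.positions.shape[0] - 1

    def squared_displacement(self) -> np.ndarray:
        """Squared distance from the origin at each step count 0..n_steps."""
        return np.sum(self.positions**2, axis=1)


def next_pseudopod_angle(
    prev_alpha: float,
    prev_side: str,
    params: PseudopodParams,
    rng: np.random.Generator,
) -> Tuple[float, str, str]:
    """Advance the decision tree one pseudopod.

    Four uniform random numbers decide, in order: split vs de novo
    (``R1 < s``), alternate vs repeat side (``R2 < a``), the side of a
    split following a de novo (``R3 < 0.5``), and the direction of a de
    novo pseudopod (``R4``).  The projected mean direction is
    ``prev_alpha +/- phi`` for splits (left positive) or uniform for de
    novo; the emitted direction adds a von Mises deviate with the
    parameters' ``sigma_phi``.

    Returns ``(alpha, kind, side)`` with ``alpha`` in degrees.
    """
    r1, r2, r3, r4 = rng.random(4)
    if r1 < params.s:
        kind = "split"
        if prev_side == SIDE_NONE:
            side = SIDE_RIGHT if r3 < 0.5 else SIDE_LEFT
        else:
            alternate = r2 < params.a
            if alternate:
                side = SIDE_LEFT if prev_side == SIDE_RIGHT else SIDE_RIGHT
            else:
                side = prev_side
        sign = 1.0 if side == SIDE_LEFT else -1.0
        mean = prev_alpha + sign * params.phi
    else:
        kind = "de_novo"
        side = SIDE_NONE
        mean = -180.0 + 360.0 * r4

    if params.sigma_phi > 0:
        mean += math.degrees(rng.vonmises(0.0, params.kappa))
    return normalize_angle(mean), kind, side


def simulate_trajectory(
    params: PseudopodParams,
    n_steps: int,
    seed=None,
    step_interval_s: float = DEFAULT_STEP_INTERVAL_S,
    growth_time_s: float = DEFAULT_GROWTH_TIME_S,
) -> Tuple[Trajectory, List[PseudopodEvent]]:
    """Simulate a single cell for ``n_steps`` pseudopodia.

    The first pseudopod points in a uniformly random direction; every
    subsequent one follows :func:`next_pseudopod_angle`.  All steps have
    length ``lambda_p`` exactly.  Event times use a constant synthetic
    clock (one pseudopod per ``step_interval_s`` seconds).
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    alpha = normalize_angle(-180.0 + 360.0 * rng.random())
    side = SIDE_NONE
    kind = "de_novo"  # the initial random pseudopod carries no side memory

    positions = np.zeros((n_steps + 1, 2))
    events: List[PseudopodEvent] = []
    for i in range(1, n_steps + 1):
        if i > 1:
            alpha, kind, side = next_pseudopod_angle(alpha, side, params, rng)
        dx = params.lambda_p * math.cos(math.radians(alpha))
        dy = params.lambda_p * math.sin(math.radians(alpha))
        positions[i] = positions[i - 1] + (dx, dy)
        t0 = (i - 1) * step_interval_s
        events.append(
            PseudopodEvent(
                index=i,
                kind=kind,
                side=side,
                alpha=alpha,
                x_start=positions[i - 1, 0],
                y_start=positions[i - 1, 1],
                x_end=positions[i, 0],
                y_end=positions[i, 1],
                t_start=t0,
                t_end=t0 + growth_time_s,
            )
        )
    return Trajectory(positions), events


def _simulate_block(
    params: PseudopodParams,
    n_traj: int,
    n_steps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised kernel: positions of ``n_traj`` cells, shape (n_traj, n_steps+1, 2).

    Implements exactly the same decision tree as
    :func:`next_pseudopod_angle`, with all trajectories advanced in
    lock-step.
    """
    phi = params.phi
    sigma = params.sigma_phi
    noisy = sigma > 0
    kappa = params.kappa if noisy else None

    alpha = -180.0 + 360.0 * rng.random(n_traj)
    # side encoded as +1 (L), -1 (R), 0 (none)
    side = np.zeros(n_traj)

    pos = np.zeros((n_traj, n_steps + 1, 2))
    rad = np.radians(alpha)
    pos[:, 1, 0] = params.lambda_p * np.cos(rad)
    pos[:, 1, 1] = params.lambda_p * np.sin(rad)

    for step in range(2, n_steps + 1):
        r1 = rng.random(n_traj)
        r2 = rng.random(n_traj)
        r3 = rng.random(n_traj)
        r4 = rng.random(n_traj)
        split = r1 < params.s
        new_side = np.where(
            side != 0.0,
            np.where(r2 < params.a, -side, side),
            np.where(r3 < 0.5, -1.0, 1.0),
        )
        mean = np.where(split, alpha + new_side * phi, -180.0 + 360.0 * r4)
        if noisy:
            mean = mean + np.degrees(rng.vonmises(0.0, kappa, n_traj))
        alpha = mean
        side = np.where(split, new_side, 0.0)
        rad = np.radians(alpha)
        pos[:, step, 0] = pos[:, step - 1, 0] + params.lambda_p * np.cos(rad)
        pos[:, step, 1] = pos[:, step - 1, 1] + params.lambda_p * np.sin(rad)
    return pos


def simulate_ensemble(
    params: PseudopodParams,
    n_traj: int,
    n_steps: int,
    seed=None,
    chunk_size: int = 25_000,
) -> Iterator[np.ndarray]:
    """Yield position blocks for an ensemble of independent trajectories.

    Blocks of up to ``chunk_size`` trajectories are generated from
    independent child streams spawned from the master seed, so results
    are reproducible for a fixed ``(seed, chunk_size)`` and the ensemble
    can be consumed streamingly without holding all positions in memory.

    Each yielded array has shape ``(block, n_steps + 1, 2)``.
    """
    if n_traj < 1:
        raise ValueError(f"n_traj must be >= 1, got {n_traj}")
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    if chunk_size < 1:
        raise ValueError(f"chunk_size must be >= 1, got {chunk_size}")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    n_chunks = (n_traj + chunk_size - 1) // chunk_size
    children = ss.spawn(n_chunks)
    remaining = n_traj
    for child in children:
        block = min(chunk_size, remaining)
        remaining -= block
        yield _simulate_block(params, block, n_steps, np.random.default_rng(child))
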
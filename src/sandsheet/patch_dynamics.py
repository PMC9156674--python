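"""State-transition simulator of Callitris grove patch dynamics under fire.

A landscape is a lattice of independent patches, each in one of six states:
a healthy fire-excluding grove, a degraded grove invaded by grass, a
recovering stand with abundant regeneration, an isolated singleton tree, a
new cohort of seedlings/saplings, or absent (no Callitris). Each year every
patch moves according to a row-stochastic transition matrix whose entries
depend on the annual burn probability f of a patch: as f rises, transitions
toward degradation and loss strengthen and transitions toward recovery and
establishment weaken.

No published probabilities anchor this model — the conceptual diagram it
formalizes indicates only relative likelihoods — so the shipped default
parameterization is for demonstration and property-based exploration only;
conclusions should rest on monotone, qualitative behavior (e.g. long-run
grove occupancy falling as fire frequency rises), not on the default numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

STATES: tuple[str, ...] = ("healthy", "degraded", "recovering", "singleton", "new", "absent")
STATE_INDEX = {s: i for i, s in enumerate(STATES)}

#: States whose inflow should strengthen with fire frequency.
FIRE_FAVORED = ("degraded", "absent")
#: States whose inflow should weaken with fire frequency.
FIRE_DISFAVORED = ("healthy", "recovering", "new")

_POWER_TOL = 1e-12
_POWER_MAX_ITER = 1_000_000


@dataclass
class TransitionModel:
    """Row-stochastic annual transition matrix over the six grove states."""

    matrix: np.ndarray
    fire_frequency: float | None = None

    def __post_init__(self) -> None:
        P = np.asarray(self.matrix, dtype=float)
        if P.shape != (len(STATES), len(STATES)):
            raise ValueError(f"matrix must be {len(STATES)}x{len(STATES)}")
        if (P < 0).any() or (P > 1).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every row must sum to 1")
        self.matrix = P

    @classmethod
    def from_fire_frequency(
        cls,
        f: float,
        entry_functions: dict[tuple[str, str], Callable[[float], float]] | None = None,
    ) -> "TransitionModel":
        """Build the matrix from f in [0, 1] via per-entry monotone templates.

        ``entry_functions`` maps (from_state, to_state) to a function of f;
        unspecified off-diagonal entries are 0 and the diagonal absorbs the
        remainder. Without ``entry_functions`` the documented demonstration
        parameterization is used.
        """
        if not 0 <= f <= 1:
            raise ValueError("fire frequency must lie in [0, 1]")
        funcs = entry_functions if entry_functions is not None else DEFAULT_ENTRY_FUNCTIONS
        P = np.zeros((len(STATES), len(STATES)))
        for (a, b), fn in funcs.items():
            P[STATE_INDEX[a], STATE_INDEX[b]] = fn(f)
        off = P.sum(axis=1) - np.diag(P)
        if (off > 1 + 1e-9).any():
            raise ValueError("off-diagonal transition mass exceeds 1; check templates")
        np.fill_diagonal(P, 1.0 - off)
        return cls(matrix=np.clip(P, 0.0, 1.0), fire_frequency=f)


#: Demonstration templates. Fire damage drives healthy->degraded and kills
#: recovering/new cohorts and singletons; fire-free years let degraded stands
#: recover, singletons seed new groves, and seedling cohorts establish.
DEFAULT_ENTRY_FUNCTIONS: dict[tuple[str, str], Callable[[float], float]] = {
    ("healthy", "degraded"): lambda f: 0.5 * f,
    ("degraded", "absent"): lambda f: 0.3 * f,
    ("degraded", "singleton"): lambda f: 0.2 * f,
    ("degraded", "recovering"): lambda f: 0.25 * (1 - f),
    ("recovering", "healthy"): lambda f: 0.3 * (1 - f),
    ("recovering", "degraded"): lambda f: 0.6 * f,
    ("singleton", "absent"): lambda f: 0.1 * f + 0.02,
    ("singleton", "new"): lambda f: 0.25 * (1 - f),
    ("new", "healthy"): lambda f: 0.2 * (1 - f),
    ("new", "absent"): lambda f: 0.7 * f,
    ("absent", "new"): lambda f: 0.1 * (1 - f),
}


def default_model(f: float) -> TransitionModel:
    """The demonstration model at fire frequency ``f`` (not field-calibrated)."""
    return TransitionModel.from_fire_frequency(f)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def step(states: np.ndarray, model: TransitionModel, rng: np.random.Generator) -> np.ndarray:
    """Advance every patch one year; patches transition independently."""
    states = np.asarray(states)
    cum = np.cumsum(model.matrix, axis=1)
    u = rng.random(states.shape)
    return (u[..., None] > cum[states]).sum(axis=-1)


def stationary_distribution(
    model: TransitionModel, tol: float = _POWER_TOL
) -> tuple[np.ndarray, bool]:
    """Limiting state distribution pi with pi P = pi, by damped power iteration.

    Returns (pi, irreducible_like): the flag is False when the limit places
    zero mass on some state (e.g. an absorbing 'absent' state drains the
    chain), in which case pi is the absorbing-limit distribution.
    """
    P = model.matrix
    pi = np.full(len(STATES), 1.0 / len(STATES))
    for _ in range(_POWER_MAX_ITER):
        nxt = 0.5 * pi + 0.5 * (pi @ P)  # damping defeats periodicity
        if np.abs(nxt - pi).max() < tol:
            pi = nxt
            break
        pi = nxt
    pi = pi / pi.sum()
    return pi, bool((pi > 1e-9).all())


@dataclass
class MosaicTrajectory:
    """Yearly state of every patch plus landscape-level state proportions."""

    states: np.ndarray  # (years + 1, n_patches) int codes into STATES
    proportions: pd.DataFrame  # index: year offset, columns: state names


def simulate_mosaic(
    model: TransitionModel,
    n_patches: int,
    years: int,
    seed: int | None = None,
    initial: np.ndarray | str = "healthy",
) -> MosaicTrajectory:
    """Seeded trajectory of an ``n_patches`` lattice over ``years`` annual steps."""
    if years < 1:
        raise ValueError("years must be at least 1")
    if n_patches < 1:
        raise ValueError("need at least one patch")
    rng = np.random.default_rng(seed)
    if isinstance(initial, str):
        state = np.full(n_patches, STATE_INDEX[initial], dtype=np.int64)
    else:
        state = np.asarray(initial, dtype=np.int64).copy()
        if state.shape != (n_patches,):
            raise ValueError("initial states shape mismatch")
    traj = np.empty((years + 1, n_patches), dtype=np.int8)
    traj[0] = state
    for t in range(1, years + 1):
        state = step(state, model, rng)
        traj[t] = state
    counts = np.stack([(traj == i).mean(axis=1) for i in range(len(STATES))], axis=1)
    props = pd.DataFrame(counts, columns=list(STATES))
    props.index.name = "year"
    return MosaicTrajectory(states=traj, proportions=props)


def grove_occupancy(traj: MosaicTrajectory, tail_years: int = 100) -> float:
    """Mean healthy-grove proportion over the trajectory's final years."""
    return float(traj.proportions["healthy"].tail(tail_years).mean())
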
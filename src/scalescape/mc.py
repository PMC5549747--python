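"""Zero-temperature downhill Monte Carlo search over affinity-scale space.

The search minimizes the proteome-average Pearson correlation <R> between
mRNA nucleobase-density profiles and scale-weighted cognate protein profiles.
It starts from the all-equal scale (fitness 0 under the flat-profile
convention) and repeatedly perturbs 1–4 randomly chosen weights by offsets
drawn uniformly from [-amplitude, +amplitude]; a move is accepted iff it
strictly lowers <R> (zero-temperature Metropolis). The amplitude is annealed
linearly from 0.1 down to 0.01 over the run. Raw weights are unconstrained
during the search; final scales are reported unit-rescaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .profiles import NucleobaseTarget, ProfileCache
from .scales import AffinityScale, rescale_unit


@dataclass(frozen=True)
class MCConfig:
    """Parameters of one Monte Carlo run.

    ``n_steps`` is the total number of *attempted* moves. Defaults follow the
    rule that a run should last at least 3x the typical number of moves to
    convergence (~300–350 on a bacterial proteome for the purine target).
    ``shared_offset=True`` applies one common offset to all perturbed entries
    of a move instead of independent offsets.
    """

    n_steps: int = 1500
    k_min: int = 1
    k_max: int = 4
    amp_start: float = 0.1
    amp_end: float = 0.01
    target: NucleobaseTarget = NucleobaseTarget.PUR
    seed: int = 0
    record_every: int = 1
    shared_offset: bool = False

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not (self.amp_start >= self.amp_end > 0):
            raise ValueError("need amp_start >= amp_end > 0")
        if not (1 <= self.k_min <= self.k_max <= 20):
            raise ValueError("need 1 <= k_min <= k_max <= 20")


@dataclass(frozen=True)
class MCState:
    """One recorded step: the proposal outcome and the current best."""

    step: int
    amplitude: float
    proposal_R: float
    accepted: bool
    current_R: float


@dataclass
class MCTrajectory:
    """The sequence of accepted scales and <R> values from one seeded run."""

    config: MCConfig
    states: list[MCState] = field(default_factory=list)
    #: (attempted-move index, <R>, raw scale vector) for the start + each acceptance
    accepted: list[tuple[int, float, np.ndarray]] = field(default_factory=list)

    @property
    def final_R(self) -> float:
        return self.accepted[-1][1]

    @property
    def final_scale(self) -> AffinityScale:
        """Best scale of the run, unit-rescaled."""
        return rescale_unit(
            AffinityScale.from_vector(
                self.accepted[-1][2],
                target=self.config.target.name,
                meta=f"mc seed={self.config.seed}",
            )
        )


def anneal_amplitude(step: int, config: MCConfig) -> float:
    """Perturbation amplitude at an attempted move: linear ramp amp_start -> amp_end."""
    if not (0 <= step < config.n_steps):
        raise ValueError(f"step {step} outside [0, {config.n_steps})")
    if config.n_steps == 1:
        return config.amp_start
    frac = step / (config.n_steps - 1)
    return config.amp_start + (config.amp_end - config.amp_start) * frac


def propose(
    weights: np.ndarray,
    amplitude: float,
    rng: np.random.Generator,
    k_min: int = 1,
    k_max: int = 4,
    shared_offset: bool = False,
) -> np.ndarray:
    """Perturb k ~ U{k_min..k_max} distinct weights by uniform offsets.

    Offsets are independent per perturbed entry by default; with
    ``shared_offset`` a single offset is applied to all of them. The input
    vector is not mutated.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be > 0")
    k = int(rng.integers(k_min, k_max + 1))
    idx = rng.choice(20, size=k, replace=False)
    out = weights.copy()
    if shared_offset:
        out[idx] += rng.uniform(-amplitude, amplitude)
    else:
        out[idx] += rng.uniform(-amplitude, amplitude, size=k)
    return out


def accept(old_R: float, new_R: float) -> bool:
    """Zero-temperature downhill criterion: accept iff strictly lower <R>; ties rejected."""
    if not (np.isfinite(old_R) and np.isfinite(new_R)):
        raise ValueError("non-finite fitness")
    return new_R < old_R


def run_mc(cache: ProfileCache, config: MCConfig) -> MCTrajectory:
    """Run one seeded Monte Carlo search and record its trajectory.

    Deterministic for fixed (cache, config): the run uses a PCG64 generator
    seeded with ``config.seed`` and nothing else.
    """
    rng = np.random.Generator(np.random.PCG64(config.seed))
    weights = np.zeros(20)
    current_R = cache.mean_R(weights, config.target)  # 0 by the flat-profile convention
    traj = MCTrajectory(config=config)
    traj.accepted.append((0, current_R, weights.copy()))
    for step in range(config.n_steps):
        amplitude = anneal_amplitude(step, config)
        proposal = propose(
            weights, amplitude, rng,
            k_min=config.k_min, k_max=config.k_max,
            shared_offset=config.shared_offset,
        )
        proposal_R = cache.mean_R(proposal, config.target)
        accepted = accept(current_R, proposal_R)
        if accepted:
            weights = proposal
            current_R = proposal_R
            traj.accepted.append((step + 1, current_R, weights.copy()))
        if (step + 1) % config.record_every == 0 or step == config.n_steps - 1:
            traj.states.append(
                MCState(step + 1, amplitude, proposal_R, accepted, current_R)
            )
    return traj


def moves_to_threshold(
    trajectory: MCTrajectory, threshold: float, count: str = "attempted"
) -> int | None:
    """First move index at which <R> <= threshold, or None if never reached.

    ``count="attempted"`` (default) returns the 1-based index of the
    attempted move that first reached the threshold (0 if the starting scale
    already satisfies it); ``count="accepted"`` counts acceptances instead.
    """
    if count not in ("attempted", "accepted"):
        raise ValueError("count must be 'attempted' or 'accepted'")
    for rank, (step, R, _) in enumerate(trajectory.accepted):
        if R <= threshold:
            return step if count == "attempted" else rank
    return None


def select_scale_at_level(
    trajectory: MCTrajectory, level: float, tolerance: float = 0.01
) -> AffinityScale | None:
    """The accepted scale whose <R> is closest to ``level``, unit-rescaled.

    Returns None when even the closest accepted <R> differs from the level
    by more than ``tolerance`` — the run never visited that matching level.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    Rs = np.array([R for _, R, _ in trajectory.accepted])
    best = int(np.argmin(np.abs(Rs - level)))
    if abs(Rs[best] - level) > tolerance:
        return None
    return rescale_unit(
        AffinityScale.from_vector(
            trajectory.accepted[best][2],
            target=trajectory.config.target.name,
            meta=f"mc seed={trajectory.config.seed} level={level:g} R={Rs[best]:.6f}",
        )
    )


def run_independent(
    cache: ProfileCache,
    base_config: MCConfig,
    n_runs: int,
    base_seed: int | None = None,
) -> list[MCTrajectory]:
    """Run ``n_runs`` independent searches with seeds base_seed, base_seed+1, ..."""
    seed0 = base_config.seed if base_seed is None else base_seed
    return [
        run_mc(cache, replace(base_config, seed=seed0 + i)) for i in range(n_runs)
    ]
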
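"""Simulated annealing over cluster assignments.

Each iteration relabels one uniformly chosen sample to a uniformly chosen
cluster (possibly its current one), recomputes the objective from scratch,
and accepts the move when ``Uniform(0,1) < exp((NN - NN') / T)`` with the
cooling schedule ``T = N / (divisor * (iter + 1))`` (iterations 0-based).

A single seeded generator drives initialization, proposals, and acceptance
draws in a fixed order, so every run is replayable. Moves that do not worsen
the objective have exponent >= 0 and are accepted without consuming a
uniform draw (the probability is 1 either way).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

from nnclust.core import Assignment, DataMatrix, objective

__all__ = [
    "AnnealingConfig",
    "ClusteringResult",
    "initialize_assignment",
    "propose_move",
    "temperature",
    "accept",
    "run_nnc",
]

# exp() underflows around -745; below this the move is effectively never taken
_MIN_EXPONENT = -745.0

DEFAULT_ITERATIONS = 20_000


@dataclass(frozen=True)
class AnnealingConfig:
    """Parameters of one annealing run.

    ``report="final"`` returns the assignment held at the last iteration;
    ``report="best"`` returns the lowest-objective assignment ever visited.
    Both objectives are always recorded in the result.
    """

    K: int
    iterations: int = DEFAULT_ITERATIONS
    seed: int = 0
    report: str = "final"
    schedule_divisor: float = 100.0
    record_trajectory: bool = False

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if self.iterations < 1:
            raise ValueError(f"iterations must be >= 1, got {self.iterations}")
        if self.report not in ("final", "best"):
            raise ValueError(f"report must be 'final' or 'best', got {self.report!r}")
        if self.schedule_divisor <= 0:
            raise ValueError("schedule_divisor must be positive")


@dataclass(frozen=True)
class ClusteringResult:
    assignment: Assignment
    final_assignment: Assignment
    best_assignment: Assignment
    final_NN: float
    best_NN: float
    initial_NN: float
    config: AnnealingConfig
    # per-iteration records (iter, T, NN_current, NN_best, accepted) if requested
    trajectory: list[tuple[int, float, float, float, bool]] = field(default_factory=list)


def initialize_assignment(n: int, K: int, rng: np.random.Generator) -> Assignment:
    """Draw each of the n labels independently and uniformly from {0..K-1}."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if K > n:
        import warnings

        warnings.warn(
            f"K={K} exceeds n={n}; some clusters are necessarily empty",
            UserWarning,
            stacklevel=2,
        )
    return Assignment(labels=rng.integers(0, K, size=n), K=K)


def propose_move(A: Assignment, rng: np.random.Generator) -> tuple[Assignment, int]:
    """Relabel one uniformly chosen sample to a uniformly chosen cluster.

    The new label may equal the old one (a no-op proposal); the two draws
    always happen, keeping the RNG stream aligned across iterations.
    """
    i = int(rng.integers(0, A.n))
    new_label = int(rng.integers(0, A.K))
    labels = A.labels.copy()
    labels[i] = new_label
    return Assignment(labels=labels, K=A.K), i


def temperature(iteration: int, N: int, divisor: float = 100.0) -> float:
    """Cooling schedule ``N / (divisor * (iteration + 1))``, iteration 0-based."""
    if not 0 <= iteration < N:
        raise ValueError(f"iteration {iteration} out of range [0, {N})")
    return N / (divisor * (iteration + 1.0))


def accept(NN: float, NN_prime: float, T: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: accept iff ``Uniform(0,1) < exp((NN - NN') / T)``.

    Non-worsening moves (exponent >= 0) are accepted unconditionally without
    drawing, since exp(x) >= 1 beats any Uniform(0,1) variate.
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    if not (math.isfinite(NN) and math.isfinite(NN_prime)):
        raise ValueError("objectives must be finite")
    exponent = (NN - NN_prime) / T
    if exponent >= 0:
        return True
    if exponent < _MIN_EXPONENT:
        exponent = _MIN_EXPONENT
    return bool(rng.uniform() < math.exp(exponent))


def run_nnc(M: DataMatrix, config: AnnealingConfig) -> ClusteringResult:
    """Anneal an assignment of M's rows into ``config.K`` clusters.

    Runs exactly ``config.iterations`` propose/evaluate/accept steps and
    tracks the best assignment seen. Fully deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    N = config.iterations

    A = initialize_assignment(M.n, config.K, rng)
    current_NN = objective(A, M)
    initial_NN = current_NN
    best_A, best_NN = A, current_NN

    trajectory: list[tuple[int, float, float, float, bool]] = []
    for iteration in range(N):
        A_prime, _ = propose_move(A, rng)
        NN_prime = objective(A_prime, M)
        T = temperature(iteration, N, config.schedule_divisor)
        accepted = accept(current_NN, NN_prime, T, rng)
        if accepted:
            A, current_NN = A_prime, NN_prime
            if current_NN < best_NN:
                best_A, best_NN = A, current_NN
        if config.record_trajectory:
            trajectory.append((iteration, T, current_NN, best_NN, accepted))

    reported = best_A if config.report == "best" else A
    return ClusteringResult(
        assignment=reported,
        final_assignment=A,
        best_assignment=best_A,
        final_NN=current_NN,
        best_NN=best_NN,
        initial_NN=initial_NN,
        config=config,
        trajectory=trajectory,
    )
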
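"""Estimate the original number of transcript molecules from an observed SPP.

An observed starting-point profile is sum-normalized and converted into an
empirical cumulative distribution function (ECDF) over its per-position
values.  A reference set maps candidate molecule numbers M to pooled ECDFs of
repeated simulations; the predicted M is the one whose pooled ECDF lies
closest to the test ECDF under the squared-difference-times-interval-width
distance

    d(E_m, E_d) = sum_{i=1}^{n-1} (E_m(x_i) - E_d(x_i))^2 (x_{i+1} - x_i)

over the sorted unique union x of both ECDFs' value lists (the largest merged
value contributes no interval, exactly as printed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CoverageKind, Profile
from .simulator import SimulationConfig, simulate_spp

__all__ = [
    "ECDF",
    "ReferenceSet",
    "EstimationResult",
    "ecdf_from_profile",
    "pooled_ecdf",
    "ecdf_distance",
    "default_molecule_grid",
    "build_reference",
    "estimate_molecules",
]


@dataclass(frozen=True)
class ECDF:
    """Step ECDF: strictly increasing unique values x, cumulative probabilities p."""

    x: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        if self.x.size == 0 or self.x.size != self.p.size:
            raise ValueError("ECDF needs matching, nonempty x and p")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("ECDF x values must be strictly increasing")
        if np.any(np.diff(self.p) < 0) or not np.isclose(self.p[-1], 1.0):
            raise ValueError("ECDF probabilities must be nondecreasing and end at 1")

    @classmethod
    def from_values(cls, values: np.ndarray) -> "ECDF":
        values = np.asarray(values, dtype=float)
        x, counts = np.unique(values, return_counts=True)
        p = np.cumsum(counts) / values.size
        p[-1] = 1.0
        return cls(x, p)

    def evaluate(self, q: np.ndarray) -> np.ndarray:
        """Right-continuous step evaluation E(q); 0 left of the first value."""
        idx = np.searchsorted(self.x, np.asarray(q, dtype=float), side="right")
        padded = np.concatenate(([0.0], self.p))
        return padded[idx]


def ecdf_from_profile(profile: Profile) -> ECDF:
    """ECDF over the T sum-normalized starting-point values (zeros included)."""
    if CoverageKind(profile.kind) is not CoverageKind.START_POINT:
        raise ValueError("ecdf_from_profile expects a starting-point profile")
    values = profile.as_float()
    total = values.sum()
    if total == 0:
        raise ValueError("cannot build an ECDF from an all-zero profile")
    return ECDF.from_values(values / total)


def pooled_ecdf(profiles: list[Profile]) -> ECDF:
    """One ECDF pooling every profile's sum-normalized per-position values."""
    if not profiles:
        raise ValueError("pooled_ecdf needs at least one profile")
    T = profiles[0].T
    pooled = []
    for prof in profiles:
        if prof.T != T:
            raise ValueError(f"mixed transcript lengths in pool: {prof.T} != {T}")
        values = prof.as_float()
        total = values.sum()
        if total == 0:
            raise ValueError("cannot pool an all-zero profile")
        pooled.append(values / total)
    return ECDF.from_values(np.concatenate(pooled))


def ecdf_distance(e_m: ECDF, e_d: ECDF) -> float:
    """Squared-difference-times-interval-width distance between two ECDFs."""
    x = np.union1d(e_m.x, e_d.x)
    if x.size < 2:
        return 0.0
    xi = x[:-1]
    diff = e_m.evaluate(xi) - e_d.evaluate(xi)
    return float(np.sum(diff**2 * np.diff(x)))


def default_molecule_grid(
    low: int = 50, high: int = 50_000, n: int = 43
) -> list[int]:
    """Log-spaced molecule-number grid inclusive of both endpoints."""
    grid = np.unique(np.round(np.geomspace(low, high, n)).astype(int))
    return [int(m) for m in grid]


@dataclass
class ReferenceSet:
    """Pooled reference ECDFs per candidate molecule number, one shared config."""

    grid: list[int]
    ecdfs: dict[int, ECDF]
    config: SimulationConfig  # config of the simulations (M field is per-grid-point)
    n_rep: int
    seed: int

    def __post_init__(self) -> None:
        if sorted(self.grid) != list(self.grid) or len(set(self.grid)) != len(self.grid):
            raise ValueError("molecule grid must be strictly increasing")
        missing = [m for m in self.grid if m not in self.ecdfs]
        if missing:
            raise ValueError(f"reference missing ECDFs for M={missing}")


@dataclass
class EstimationResult:
    """Predicted molecule number with the full per-M distance table."""

    predicted: int
    distances: dict[int, float]
    tie: bool


def build_reference(
    config: SimulationConfig,
    grid: list[int],
    n_rep: int = 100,
) -> ReferenceSet:
    """Simulate n_rep experiments per grid M and pool their SPP ECDFs.

    Deterministic given ``config.seed``: child seeds are spawned per
    (grid point, repetition) from a single SeedSequence.
    """
    grid = [int(m) for m in grid]
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(len(grid))
    ecdfs: dict[int, ECDF] = {}
    for m, child in zip(grid, children):
        rngs = [np.random.default_rng(s) for s in child.spawn(n_rep)]
        profiles = [
            simulate_spp(
                SimulationConfig(config.model, M=m, S=config.S,
                                 pcr_cycles=config.pcr_cycles, seed=config.seed),
                rng=rng,
            )
            for rng in rngs
        ]
        ecdfs[m] = pooled_ecdf(profiles)
    return ReferenceSet(grid=grid, ecdfs=ecdfs, config=config, n_rep=n_rep,
                        seed=config.seed)


def estimate_molecules(test: "Profile | ECDF", ref: ReferenceSet) -> EstimationResult:
    """Predict M as the grid point whose pooled ECDF is nearest the test ECDF.

    Ties are broken toward the smaller M (conservative copy-number estimate).
    """
    if not ref.grid:
        raise ValueError("empty reference set")
    test_ecdf = test if isinstance(test, ECDF) else ecdf_from_profile(test)
    distances = {m: ecdf_distance(test_ecdf, ref.ecdfs[m]) for m in ref.grid}
    best = min(distances.values())
    winners = [m for m in ref.grid if distances[m] == best]
    return EstimationResult(predicted=min(winners), distances=distances,
                            tie=len(winners) > 1)
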
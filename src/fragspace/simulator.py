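"""Seeded simulation of an unbiased RNA-seq experiment on one transcript.

Pipeline: exhaustively fragment M molecules by sampling fragmentation
patterns from the (weighted) pattern space, amplify every fragment uniformly
by 2**cycles to mimic perfectly efficient PCR, sequence by drawing S
fragments from the amplified pool without replacement, and summarize the
sequenced fragments as observed coverage profiles.

Pattern sampling is exact: at remaining suffix length ``l >= F_1`` a pair
(gap g, length F_j) is chosen with probability proportional to
``W(F_j) * mass(l - g - F_j)`` where ``mass`` is the (weighted) suffix
pattern mass, so in the unweighted case every pattern of the space is drawn
with probability exactly ``1 / FP``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .model import (
    CoverageKind,
    ModelValidationError,
    PatternSpaceModel,
    Profile,
    WeightMode,
    coverage_vector,
)
from .oracle import FragmentationPattern
from .pattern_space import mass_table, pattern_count_table

__all__ = [
    "SimulationConfig",
    "SimulatedLibrary",
    "sample_pattern",
    "fragment_molecules",
    "amplify",
    "sample_sequenced",
    "observed_profiles",
    "simulate_spp",
]

# Batch sampling keeps a dense (T+1, n_candidates) cumulative table when the
# candidate set (F_1 * k) is small; otherwise falls back to per-suffix rows.
_DENSE_CANDIDATE_LIMIT = 2048


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated experiment.

    M molecules are fragmented, amplified by ``2**pcr_cycles``, and S
    fragments are sequenced.  All randomness flows from ``seed`` through a
    single numpy Generator in documented order (fragmentation first, then
    sequencing).
    """

    model: PatternSpaceModel
    M: int
    S: int = 100_000
    pcr_cycles: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ModelValidationError(f"M must be >= 1, got {self.M}")
        if self.S < 1:
            raise ModelValidationError(f"S must be >= 1, got {self.S}")
        if self.pcr_cycles < 0:
            raise ModelValidationError(f"pcr_cycles must be >= 0, got {self.pcr_cycles}")


@dataclass
class SimulatedLibrary:
    """Multiset of fragment species (start, length) with integer multiplicities."""

    starts: np.ndarray
    lengths: np.ndarray
    multiplicities: np.ndarray
    stage: str  # fragmented | amplified | sequenced
    model: PatternSpaceModel

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.multiplicities = np.asarray(self.multiplicities, dtype=np.int64)

    @property
    def total(self) -> int:
        return int(self.multiplicities.sum())

    def species(self) -> list[tuple[int, int, int]]:
        return [
            (int(s), int(f), int(m))
            for s, f, m in zip(self.starts, self.lengths, self.multiplicities)
        ]


# ---------------------------------------------------------------------------
# sampling tables
# ---------------------------------------------------------------------------

class _SamplerTables:
    """Per-suffix-length candidate tables for exact sequential sampling.

    For suffix length l >= F_1 the candidates are all (g, j) with
    g in 0..F_1-1 and l - g - F_j >= 0; candidate probability is
    W_j * mass(l - g - F_j) / mass(l).  Unweighted masses are exact big
    integers, so probabilities are exact up to one float division.
    """

    def __init__(self, model: PatternSpaceModel):
        self.model = model
        T, F1, lengths = model.T, model.F1, model.lengths
        if model.is_weighted:
            mass = mass_table(model)
            weights = model.weights
        else:
            mass = pattern_count_table(T, lengths)
            weights = tuple(1 for _ in lengths)
        gs, js = [], []
        for g in range(F1):
            for j in range(len(lengths)):
                gs.append(g)
                js.append(j)
        self.cand_g = np.array(gs, dtype=np.int64)
        self.cand_j = np.array(js, dtype=np.int64)
        self.cand_F = np.array([lengths[j] for j in js], dtype=np.int64)
        self._mass = mass
        self._weights = weights
        self._rows: dict[int, np.ndarray] = {}
        self.n_cand = len(gs)
        self.dense: np.ndarray | None = None
        if self.n_cand <= _DENSE_CANDIDATE_LIMIT:
            dense = np.zeros((T + 1, self.n_cand))
            for l in range(F1, T + 1):
                dense[l] = self._cum_row(l)
            self.dense = dense

    def _cum_row(self, l: int) -> np.ndarray:
        probs = np.zeros(self.n_cand)
        total = self._mass[l]
        for c in range(self.n_cand):
            rem = l - self.cand_g[c] - self.cand_F[c]
            if rem >= 0:
                w = self._weights[self.cand_j[c]]
                probs[c] = (w * self._mass[rem]) / total if total else 0.0
        cum = np.cumsum(probs)
        if cum[-1] > 0:
            cum /= cum[-1]
        cum[-1] = 1.0
        return cum

    def cum_row(self, l: int) -> np.ndarray:
        if self.dense is not None:
            return self.dense[l]
        row = self._rows.get(l)
        if row is None:
            row = self._rows[l] = self._cum_row(l)
        return row


@lru_cache(maxsize=64)
def _tables_for(model: PatternSpaceModel) -> _SamplerTables:
    return _SamplerTables(model)


def _sampling_model(model: PatternSpaceModel) -> PatternSpaceModel:
    """Sampling interprets weights as pattern mass (pattern mode)."""
    if model.is_weighted and model.weight_mode is not WeightMode.PATTERN:
        return replace_weight_mode(model, WeightMode.PATTERN)
    return model


def replace_weight_mode(model: PatternSpaceModel, mode: WeightMode) -> PatternSpaceModel:
    return PatternSpaceModel(
        model.T, model.lengths, weights=model.weights,
        read_length=model.read_length, weight_mode=mode,
    )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def sample_pattern(rng: np.random.Generator, model: PatternSpaceModel) -> FragmentationPattern:
    """Draw one exhaustive fragmentation pattern.

    Unweighted models return every pattern with probability 1/FP; weighted
    models sample proportionally to pattern mass (product of fragment weights).
    """
    tables = _tables_for(_sampling_model(model))
    F1 = model.F1
    pos = 0
    placements: list[tuple[int, int]] = []
    while model.T - pos >= F1:
        l = model.T - pos
        cum = tables.cum_row(l)
        c = int(np.searchsorted(cum, rng.random(), side="right"))
        g = int(tables.cand_g[c])
        F = int(tables.cand_F[c])
        placements.append((pos + g, F))
        pos += g + F
    return FragmentationPattern(tuple(placements))


def _fragment_counts_batch(
    rng: np.random.Generator, model: PatternSpaceModel, n_molecules: int
) -> np.ndarray:
    """Vectorized sampling of n_molecules patterns; returns (k, T) start counts."""
    tables = _tables_for(_sampling_model(model))
    T, F1, k = model.T, model.F1, model.k
    counts = np.zeros((k, T), dtype=np.int64)
    pos = np.zeros(n_molecules, dtype=np.int64)
    active = np.arange(n_molecules)
    while active.size:
        rem = T - pos[active]
        u = rng.random(active.size)
        if tables.dense is not None:
            rows = tables.dense[rem]
            idx = (rows < u[:, None]).sum(axis=1)
        else:
            idx = np.empty(active.size, dtype=np.int64)
            for l in np.unique(rem):
                mask = rem == l
                idx[mask] = np.searchsorted(tables.cum_row(int(l)), u[mask], side="right")
        g = tables.cand_g[idx]
        F = tables.cand_F[idx]
        j = tables.cand_j[idx]
        starts = pos[active] + g
        np.add.at(counts, (j, starts), 1)
        pos[active] += g + F
        active = active[T - pos[active] >= F1]
    return counts


def fragment_molecules(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedLibrary:
    """Exhaustively fragment M molecules; pool fragments into a library."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    model = config.model
    counts = _fragment_counts_batch(rng, model, config.M)
    j_idx, starts = np.nonzero(counts)
    return SimulatedLibrary(
        starts=starts,
        lengths=np.array(model.lengths, dtype=np.int64)[j_idx],
        multiplicities=counts[j_idx, starts],
        stage="fragmented",
        model=model,
    )


def amplify(library: SimulatedLibrary, pcr_cycles: int) -> SimulatedLibrary:
    """Uniform, perfectly efficient PCR: every multiplicity times 2**cycles."""
    if library.stage != "fragmented":
        raise ValueError(f"amplify expects a 'fragmented' library, got {library.stage!r}")
    if pcr_cycles < 0:
        raise ModelValidationError("pcr_cycles must be >= 0")
    return SimulatedLibrary(
        starts=library.starts.copy(),
        lengths=library.lengths.copy(),
        multiplicities=library.multiplicities * (2 ** pcr_cycles),
        stage="amplified",
        model=library.model,
    )


def sample_sequenced(
    rng: np.random.Generator, library: SimulatedLibrary, S: int
) -> SimulatedLibrary:
    """Sequence S fragments drawn without replacement from the amplified pool."""
    if library.stage != "amplified":
        raise ValueError(f"sample_sequenced expects an 'amplified' library, got {library.stage!r}")
    total = library.total
    if S > total:
        raise ValueError(f"cannot sequence S={S} fragments from a pool of {total}")
    if total < 10**9:
        drawn = rng.multivariate_hypergeometric(
            library.multiplicities, S, method="marginals"
        )
    else:
        # Pool too large for numpy's hypergeometric kernels: draw S distinct
        # item indices uniformly from the pool (rejection on duplicates; S is
        # tiny relative to the pool, so redraws are rare) and bin by species.
        # Distributionally identical to multivariate hypergeometric sampling.
        cum = np.cumsum(library.multiplicities)
        picks = np.unique(rng.integers(0, total, size=S))
        while picks.size < S:
            extra = rng.integers(0, total, size=S - picks.size)
            picks = np.unique(np.concatenate([picks, extra]))
        species = np.searchsorted(cum, picks, side="right")
        drawn = np.bincount(species, minlength=library.multiplicities.size)
    keep = drawn > 0
    return SimulatedLibrary(
        starts=library.starts[keep],
        lengths=library.lengths[keep],
        multiplicities=drawn[keep],
        stage="sequenced",
        model=library.model,
    )


def observed_profiles(
    library: SimulatedLibrary, kind: CoverageKind, R: int | None = None
) -> Profile:
    """Observed coverage profile (raw counts) of the library's fragments."""
    kind = CoverageKind(kind)
    model = library.model
    R = model.read_length if R is None else int(R)
    values = np.zeros(model.T, dtype=np.int64)
    if kind is CoverageKind.START_POINT:
        np.add.at(values, library.starts, library.multiplicities)
    else:
        for start, F, mult in zip(library.starts, library.lengths, library.multiplicities):
            vec = coverage_vector(kind, int(F), R)
            values[start:start + F] += vec * int(mult)
    return Profile(values.astype(object), kind, model, normalized=False)


def simulate_spp(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> Profile:
    """End-to-end run: fragment, amplify, sequence, observed starting-point profile."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    library = fragment_molecules(config, rng=rng)
    amplified = amplify(library, config.pcr_cycles)
    sequenced = sample_sequenced(rng, amplified, config.S)
    return observed_profiles(sequenced, CoverageKind.START_POINT)
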
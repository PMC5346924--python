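"""Brute-force enumeration of the fragmentation pattern space.

Ground truth for the dynamic-programming recursions and for distributional
tests of the simulator.  Exponential in T — guarded by a safety bound and
never used on transcript lengths beyond a few dozen bases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    CoverageKind,
    PatternSpaceModel,
    Profile,
    WeightMode,
    coverage_vector,
)

__all__ = ["FragmentationPattern", "enumerate_patterns", "profile_from_patterns"]

DEFAULT_SAFETY_BOUND = 25


@dataclass(frozen=True)
class FragmentationPattern:
    """One exhaustive placement: ordered, non-overlapping (start, length) pairs.

    Every gap — leading, internal, trailing — is strictly shorter than the
    smallest allowed fragment length (the placement is maximal).
    """

    placements: tuple[tuple[int, int], ...]

    def __iter__(self):
        return iter(self.placements)

    def __len__(self) -> int:
        return len(self.placements)

    def is_valid_for(self, model: PatternSpaceModel) -> bool:
        F1 = model.F1
        prev_end = 0
        for start, length in self.placements:
            if length not in model.lengths:
                return False
            if start < prev_end or start - prev_end >= F1:
                return False
            prev_end = start + length
        return prev_end <= model.T and model.T - prev_end < F1


def enumerate_patterns(
    model: PatternSpaceModel, safety_bound: int = DEFAULT_SAFETY_BOUND
) -> list[FragmentationPattern]:
    """All distinct exhaustive fragmentation patterns, depth-first by
    (gap, length) ascending.

    A transcript shorter than the smallest fragment yields the single empty
    pattern.  Refuses T above ``safety_bound`` to cap exponential growth.
    """
    if model.T > safety_bound:
        raise ValueError(
            f"enumerate_patterns refused: T={model.T} exceeds safety bound "
            f"{safety_bound}; raise safety_bound explicitly if you mean it"
        )
    F1 = model.F1
    out: list[FragmentationPattern] = []
    stack: list[tuple[int, int]] = []

    def recurse(pos: int) -> None:
        remaining = model.T - pos
        if remaining < F1:
            out.append(FragmentationPattern(tuple(stack)))
            return
        for gap in range(F1):
            for F in model.lengths:
                if gap + F <= remaining:
                    stack.append((pos + gap, F))
                    recurse(pos + gap + F)
                    stack.pop()

    recurse(0)
    return out


def profile_from_patterns(
    patterns: list[FragmentationPattern],
    kind: CoverageKind,
    model: PatternSpaceModel,
) -> Profile:
    """Position-wise sum of every fragment's coverage vector over the patterns.

    Exact integers when the model is unweighted; in contribution mode each
    fragment's vector is scaled by W(F_j), in pattern mode each pattern is
    weighted by the product of its fragments' weights.
    """
    kind = CoverageKind(kind)
    W = model.weight_map()
    exact = not model.is_weighted
    values = [0] * model.T if exact else np.zeros(model.T)
    for pattern in patterns:
        if model.is_weighted and model.weight_mode is WeightMode.PATTERN:
            pattern_mass = 1.0
            for _, length in pattern:
                pattern_mass *= W[length]
        else:
            pattern_mass = 1
        for start, length in pattern:
            scale = (
                pattern_mass
                if (model.is_weighted and model.weight_mode is WeightMode.PATTERN)
                else (1 if exact else W[length])
            )
            if scale == 0:
                continue
            vec = coverage_vector(kind, length, model.read_length)
            for off, v in enumerate(vec):
                if v:
                    values[start + off] += int(v) * scale
    arr = np.array(values, dtype=object if exact else float)
    return Profile(arr, kind, model, normalized=False,
                   weight_mode=model.weight_mode if model.is_weighted else None)
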
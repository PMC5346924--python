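"""Core data types shared by every fragspace module.

The model describes unbiased, exhaustive fragmentation of a single transcript:
fragments of allowed lengths are placed on non-overlapping positions until no
remaining gap (leading, internal or trailing) can hold another fragment.  All
coordinates are 0-based, half-open ``[start, start + F)`` internally; file
output is 1-based.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ModelValidationError",
    "WeightMode",
    "CoverageKind",
    "PatternSpaceModel",
    "Profile",
    "PerLengthStartMatrix",
    "coverage_vector",
]


class ModelValidationError(ValueError):
    """Raised when a model or profile violates its invariants."""


class WeightMode(str, enum.Enum):
    """How per-length weights W(F_j) enter the weighted pattern space.

    ``CONTRIBUTION``
        Patterns remain equiprobable; each fragment's coverage contribution is
        scaled by W(F_j).  This is the default and matches the arithmetic of
        weighting a coverage vector directly.
    ``PATTERN``
        Each pattern is reweighted by the product of its fragments' weights
        (pattern mass).  Used by the simulator for consistent sampling.
    """

    CONTRIBUTION = "contribution"
    PATTERN = "pattern"


class CoverageKind(str, enum.Enum):
    """Which per-fragment coverage vector a profile sums over the pattern space."""

    START_POINT = "start_point"  # SPP: 1 at the fragment's leftmost base
    FRAGMENT = "fragment"        # FCP: 1 over every base of the fragment
    READ = "read"                # RCP: R bases from each fragment end (clipped)


def _as_weight_mode(mode: "WeightMode | str") -> WeightMode:
    if isinstance(mode, WeightMode):
        return mode
    return WeightMode(str(mode))


@dataclass(frozen=True)
class PatternSpaceModel:
    """Specification of a fragmentation pattern space.

    Parameters
    ----------
    T
        Transcript length in bp (positive integer).
    lengths
        Allowed fragment lengths ``F_1 < ... < F_k`` in bp (each >= 1).
    weights
        Optional per-length weights ``W(F_j) >= 0`` (dimensionless), given as a
        mapping ``F_j -> W`` covering every length.
    read_length
        Read length R in bp; only used for read-coverage profiles.
    weight_mode
        How weights enter the weighted pattern space (see :class:`WeightMode`).
    """

    T: int
    lengths: tuple[int, ...]
    weights: tuple[float, ...] | None = None
    read_length: int = 1
    weight_mode: WeightMode = WeightMode.CONTRIBUTION

    def __init__(
        self,
        T: int,
        lengths: Sequence[int] | int,
        weights: "Mapping[int, float] | Sequence[float] | None" = None,
        read_length: int = 1,
        weight_mode: "WeightMode | str" = WeightMode.CONTRIBUTION,
    ) -> None:
        if isinstance(lengths, (int, np.integer)):
            lengths = (int(lengths),)
        lengths = tuple(int(f) for f in lengths)
        if isinstance(weights, Mapping):
            missing = [f for f in lengths if f not in weights]
            if missing:
                raise ModelValidationError(
                    f"weights missing for fragment lengths {missing}"
                )
            weights = tuple(float(weights[f]) for f in lengths)
        elif weights is not None:
            weights = tuple(float(w) for w in weights)
            if len(weights) != len(lengths):
                raise ModelValidationError(
                    "weights sequence must align with lengths"
                )
        object.__setattr__(self, "T", int(T))
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "read_length", int(read_length))
        object.__setattr__(self, "weight_mode", _as_weight_mode(weight_mode))
        self._validate()

    def _validate(self) -> None:
        if self.T <= 0:
            raise ModelValidationError(f"transcript length T must be >= 1, got {self.T}")
        if not self.lengths:
            raise ModelValidationError("at least one fragment length is required")
        if any(f < 1 for f in self.lengths):
            raise ModelValidationError(f"fragment lengths must be >= 1, got {self.lengths}")
        if any(b <= a for a, b in zip(self.lengths, self.lengths[1:])):
            raise ModelValidationError(
                f"fragment lengths must be strictly increasing (duplicates rejected), got {self.lengths}"
            )
        if self.weights is not None and any(w < 0 for w in self.weights):
            raise ModelValidationError("weights must be nonnegative")
        if self.read_length < 1:
            raise ModelValidationError(f"read length must be >= 1, got {self.read_length}")

    # -- convenience -------------------------------------------------------

    @property
    def k(self) -> int:
        return len(self.lengths)

    @property
    def F1(self) -> int:
        """Smallest fragment length; every gap must be strictly shorter."""
        return self.lengths[0]

    @property
    def is_weighted(self) -> bool:
        return self.weights is not None

    def weight_map(self) -> dict[int, float]:
        if self.weights is None:
            return {f: 1.0 for f in self.lengths}
        return dict(zip(self.lengths, self.weights))

    def with_weights(
        self,
        weights: "Mapping[int, float] | Sequence[float] | None",
        weight_mode: "WeightMode | str | None" = None,
    ) -> "PatternSpaceModel":
        return PatternSpaceModel(
            self.T,
            self.lengths,
            weights=weights,
            read_length=self.read_length,
            weight_mode=weight_mode if weight_mode is not None else self.weight_mode,
        )

    def unweighted(self) -> "PatternSpaceModel":
        return self.with_weights(None)


def coverage_vector(kind: CoverageKind, F: int, R: int = 1) -> np.ndarray:
    """Per-fragment coverage vector C of length ``F`` for the given profile kind.

    For read coverage, R bases from each end are covered; the two read
    sub-vectors are added, so for F < 2R the overlap sums to 2 and for F <= R
    the vector is constant 2 (each read clipped to the fragment).
    """
    kind = CoverageKind(kind)
    if kind is CoverageKind.START_POINT:
        vec = np.zeros(F, dtype=np.int64)
        vec[0] = 1
        return vec
    if kind is CoverageKind.FRAGMENT:
        return np.ones(F, dtype=np.int64)
    if kind is CoverageKind.READ:
        a = min(int(R), F)
        vec = np.zeros(F, dtype=np.int64)
        vec[:a] += 1
        vec[F - a:] += 1
        return vec
    raise ValueError(f"unknown coverage kind {kind!r}")  # pragma: no cover


@dataclass
class Profile:
    """A length-T per-position coverage profile over the pattern space.

    ``values`` is a numpy array of length ``model.T``: exact integers
    (object dtype) on the exact unweighted path, exact :class:`~fractions.Fraction`
    after exact normalization, float64 otherwise.
    """

    values: np.ndarray
    kind: CoverageKind
    model: PatternSpaceModel
    normalized: bool = False
    weight_mode: WeightMode | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.kind = CoverageKind(self.kind)
        if len(self.values) != self.model.T:
            raise ModelValidationError(
                f"profile length {len(self.values)} != transcript length {self.model.T}"
            )

    @property
    def T(self) -> int:
        return self.model.T

    def as_float(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def total(self):
        return self.values.sum()

    def normalize(self) -> "Profile":
        """Sum-normalize to 1; an all-zero profile is returned unchanged with a warning."""
        total = self.values.sum()
        if total == 0:
            warnings.warn(
                "profile sums to zero (no fragment fits the transcript); "
                "returning it un-normalized",
                RuntimeWarning,
                stacklevel=2,
            )
            return Profile(self.values.copy(), self.kind, self.model,
                           normalized=False, weight_mode=self.weight_mode)
        if self.values.dtype == object:
            vals = np.array([Fraction(int(v), int(total)) if isinstance(v, int)
                             else Fraction(v) / Fraction(total)
                             for v in self.values], dtype=object)
        else:
            vals = self.values / float(total)
        return Profile(vals, self.kind, self.model,
                       normalized=True, weight_mode=self.weight_mode)


@dataclass
class PerLengthStartMatrix:
    """Per-length, per-position pattern-weighted fragment start counts.

    Row j, column p holds the total (weight-scaled) count over all patterns of
    fragments of length ``lengths[j]`` starting at position p.  Summing rows
    yields the raw starting-point profile; convolving row j with the coverage
    vector for ``lengths[j]`` and summing yields any coverage profile.
    """

    lengths: tuple[int, ...]
    values: np.ndarray  # shape (k, T); object (exact ints) or float64
    model: PatternSpaceModel
    weight_mode: WeightMode | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.lengths), self.model.T):
            raise ModelValidationError(
                f"start matrix shape {self.values.shape} != "
                f"({len(self.lengths)}, {self.model.T})"
            )

    def row(self, F: int) -> np.ndarray:
        return self.values[self.lengths.index(F)]

    def spp_values(self) -> np.ndarray:
        return self.values.sum(axis=0)
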
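"""Empirical fragment-length distributions and pattern-space weights.

A fragment-length histogram is read from a two-column TSV (length, count) or
extracted from mapped paired-end alignments (absolute template length, one
count per pair, taken from the leftmost mate).  Unobserved lengths strictly
inside the observed range are linearly interpolated on counts, the result is
normalized to relative frequencies, and per-length weights are the ratio of
observed to pattern-space-expected relative frequency:

    W(F_j) = observed(F_j) / expected(F_j)

so that expected frequency times weight, renormalized, reproduces the
observed distribution on the model lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PatternSpaceModel
from .pattern_space import per_length_fragment_counts

__all__ = [
    "FragmentLengthHistogram",
    "EmpiricalLengthDistribution",
    "lengths_from_alignments",
    "interpolate_distribution",
    "expected_length_frequencies",
    "compute_weights",
    "synthetic_length_histogram",
]


@dataclass
class FragmentLengthHistogram:
    """Observed fragment-length counts with provenance."""

    counts: dict[int, int]
    provenance: str = ""
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = {int(l): int(c) for l, c in self.counts.items()}
        if any(l <= 0 for l in self.counts):
            raise ValueError("fragment lengths must be positive")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be nonnegative")
        if not any(c > 0 for c in self.counts.values()):
            raise ValueError("histogram needs at least one nonzero count")

    @property
    def min_length(self) -> int:
        return min(l for l, c in self.counts.items() if c > 0)

    @property
    def max_length(self) -> int:
        return max(l for l, c in self.counts.items() if c > 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class EmpiricalLengthDistribution:
    """Relative frequencies on the contiguous observed range, with
    interpolation flags for the unobserved interior lengths."""

    lengths: np.ndarray
    frequencies: np.ndarray
    interpolated: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        if np.any(np.diff(self.lengths) != 1):
            raise ValueError("support must be the contiguous observed range")
        if np.any(self.frequencies < 0):
            raise ValueError("frequencies must be nonnegative")
        if abs(self.frequencies.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must sum to 1")

    def frequency_of(self, length: int) -> float:
        idx = int(length) - int(self.lengths[0])
        if idx < 0 or idx >= self.lengths.size:
            raise KeyError(f"length {length} outside observed range "
                           f"[{self.lengths[0]}, {self.lengths[-1]}]")
        return float(self.frequencies[idx])

    def support(self) -> tuple[int, int]:
        return int(self.lengths[0]), int(self.lengths[-1])


def lengths_from_alignments(
    source: str, reference: str | None = None
) -> FragmentLengthHistogram:
    """Fragment-length histogram from SAM/BAM insert sizes or a TSV table.

    For alignments: one length per read pair, counted once from the leftmost
    mate (positive template length), restricted to ``reference`` when given;
    secondary/supplementary/unmapped records are ignored, and paired records
    with zero template length are skipped and tallied in ``n_skipped``.
    """
    src = str(source)
    if src.endswith((".sam", ".bam", ".cram")):
        return _lengths_from_sam(src, reference)
    table = pd.read_csv(src, sep="\t", header=None, comment="#",
                        names=["length", "count"])
    if table.empty:
        raise ValueError(f"no rows in histogram file {src}")
    counts: dict[int, int] = {}
    for length, count in zip(table["length"], table["count"]):
        counts[int(length)] = counts.get(int(length), 0) + int(count)
    return FragmentLengthHistogram(counts, provenance=src)


def _lengths_from_sam(path: str, reference: str | None) -> FragmentLengthHistogram:
    import pysam

    counts: dict[int, int] = {}
    skipped = 0
    with pysam.AlignmentFile(path, check_sq=False) as handle:
        if reference is not None and reference not in handle.references:
            raise ValueError(
                f"reference {reference!r} not in {path}; available: "
                f"{list(handle.references)}"
            )
        for rec in handle:
            if (rec.is_unmapped or not rec.is_paired or rec.is_secondary
                    or rec.is_supplementary or rec.mate_is_unmapped):
                continue
            if reference is not None and rec.reference_name != reference:
                continue
            tlen = rec.template_length
            if tlen == 0:
                skipped += 1
                continue
            if tlen < 0:  # count each pair once, from the leftmost mate
                continue
            counts[int(tlen)] = counts.get(int(tlen), 0) + 1
    if not counts:
        raise ValueError(
            f"no usable proper read pairs in {path}"
            + (f" for reference {reference!r}" if reference else "")
        )
    return FragmentLengthHistogram(counts, provenance=path, n_skipped=skipped)


def interpolate_distribution(hist: FragmentLengthHistogram) -> EmpiricalLengthDistribution:
    """Linearly interpolate unobserved interior lengths on counts, then
    normalize to relative frequencies.  Endpoints are never extrapolated."""
    observed = sorted(l for l, c in hist.counts.items() if c > 0)
    lo, hi = observed[0], observed[-1]
    grid = np.arange(lo, hi + 1)
    obs_lengths = np.array(observed, dtype=float)
    obs_counts = np.array([hist.counts[l] for l in observed], dtype=float)
    interp_counts = np.interp(grid, obs_lengths, obs_counts)
    flags = ~np.isin(grid, observed)
    freqs = interp_counts / interp_counts.sum()
    return EmpiricalLengthDistribution(grid, freqs, flags, provenance=hist.provenance)


def expected_length_frequencies(model: PatternSpaceModel) -> dict[int, float]:
    """Relative expected frequency of each fragment length in the pattern space."""
    counts = per_length_fragment_counts(model)
    total = sum(counts.values())
    return {F: c / total for F, c in counts.items()}


def compute_weights(
    observed: EmpiricalLengthDistribution,
    expected: dict[int, float],
    lengths: list[int] | tuple[int, ...],
) -> dict[int, float]:
    """W(F_j) = observed(F_j) / expected(F_j) for every model length.

    Errors if a model length lies outside either support, or if the expected
    frequency is zero where the observed one is not.
    """
    lo, hi = observed.support()
    outside = [F for F in lengths if F < lo or F > hi]
    if outside:
        raise ValueError(
            f"model lengths {outside} outside observed range [{lo}, {hi}]"
        )
    missing = [F for F in lengths if F not in expected]
    if missing:
        raise ValueError(f"model lengths {missing} missing from expected frequencies")
    weights: dict[int, float] = {}
    for F in lengths:
        obs = observed.frequency_of(F)
        exp = expected[F]
        if exp == 0:
            if obs > 0:
                raise ValueError(
                    f"length {F}: observed frequency {obs} but zero expected frequency"
                )
            import warnings

            warnings.warn(f"length {F}: zero observed and expected frequency; W=0",
                          RuntimeWarning, stacklevel=2)
            weights[F] = 0.0
        else:
            weights[F] = obs / exp
    return weights


def synthetic_length_histogram(
    mean: float = 300.0,
    sd: float = 50.0,
    low: int = 100,
    high: int = 500,
    total: int = 100_000,
) -> FragmentLengthHistogram:
    """Deterministic bell-shaped (truncated discretized normal) histogram.

    A synthetic stand-in emulating the shape of insert-size distributions seen
    in real paired-end libraries; used where no alignment data is supplied.
    """
    grid = np.arange(low, high + 1)
    dens = np.exp(-0.5 * ((grid - mean) / sd) ** 2)
    dens /= dens.sum()
    counts = np.round(dens * total).astype(int)
    counts[counts == 0] = 0
    keep = {int(l): int(c) for l, c in zip(grid, counts) if c > 0}
    return FragmentLengthHistogram(
        keep, provenance=f"synthetic truncated normal(mean={mean}, sd={sd})"
    )
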
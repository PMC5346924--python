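"""Impose an empirical insert-size distribution on the pattern space.

The enumerated pattern space strongly prefers short fragments (its length
distribution is L-shaped) while real libraries are bell-shaped.  Per-length
weights W(F_j) = observed / expected frequency transform the pattern-space
length distribution into the empirical one by construction; profiles in the
weighted space shift coverage toward the long fragments the data favors.
"""

import numpy as np

from fragspace import (
    CoverageKind,
    PatternSpaceModel,
    compute_weights,
    expected_length_frequencies,
    expected_profile,
    interpolate_distribution,
    synthetic_length_histogram,
    weighted_profile,
)

T = 1000
# Bell-shaped synthetic insert-size histogram (stands in for a real library).
hist = synthetic_length_histogram(mean=300, sd=60, low=100, high=600, total=500_000)
observed = interpolate_distribution(hist)
lo, hi = observed.support()
print(f"observed insert sizes: [{lo}, {hi}] bp, {hist.total} fragments")

model = PatternSpaceModel(T, list(range(lo, hi + 1)), read_length=100)
expected = expected_length_frequencies(model)
weights = compute_weights(observed, expected, model.lengths)
print(f"weights grow with length: W({lo})={weights[lo]:.3g}  "
      f"W(300)={weights[300]:.3g}  W({hi})={weights[hi]:.3g}")
# Long fragments are combinatorially rare in the pattern space but common in
# the data, so their weights are enormous.

# The defining identity: expected frequency x weight, renormalized, is the
# observed distribution.
transformed = np.array([expected[F] * weights[F] for F in model.lengths])
transformed /= transformed.sum()
target = np.array([observed.frequency_of(F) for F in model.lengths])
target /= target.sum()
print(f"max |transformed - observed| over lengths: "
      f"{np.abs(transformed - target).max():.2e}")

# Weighting shifts starting-point mass into the first half of the transcript:
# fragments longer than T/2 can only start there.
weighted = model.with_weights(weights)
spp_u = expected_profile(model, CoverageKind.START_POINT).normalize().as_float()
spp_w = weighted_profile(weighted, CoverageKind.START_POINT).normalize().as_float()
print(f"first-half SP mass: unweighted={spp_u[:T // 2].sum():.3f}  "
      f"weighted={spp_w[:T // 2].sum():.3f}")
# The weighted SPP is visibly asymmetric: upweighted long fragments place
# their starts exclusively in the first half.
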
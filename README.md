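# fragspace

An enumerative-combinatorics model of **unbiased RNA-seq fragmentation** for a
single transcript.  Nonuniform read coverage along transcripts is usually
blamed on library-preparation bias, but even a perfectly unbiased protocol
has a structured expected coverage: when fragmentation is *exhaustive* (every
leftover gap is too short to hold another fragment), the set of possible
fragmentation outcomes is a finite combinatorial space, and averaging over it
yields coverage profiles with characteristic peaks and edge behaviour.

`fragspace` is for computational biologists who want the bias-free baseline
against which observed nonuniformity should be judged, and for method
developers who need a null model of fragment placement.  It provides:

- **Exact pattern counting.** The number of exhaustive fragmentation
  patterns `FP(T, F_1..k)` by dynamic programming with arbitrary-precision
  integers, for a single fragment length or a range, with
  `FP(l) = Σ_{i=0}^{F_1−1} Σ_j FP(l − F_j − i)` and `FP(l) = 1` for
  `0 ≤ l ≤ F_1`.
- **Expected coverage profiles.** Starting-point (SPP), fragment-coverage
  (FCP) and read-coverage (RCP, `R` bases from each fragment end) profiles,
  exact per position, from the factorization
  `M[j, p] = FP(p)·FP(T − p − F_j)`.
- **Empirically weighted pattern spaces.** Per-length weights
  `W(F_j) = observed/expected frequency`, derived from paired-end insert
  sizes (SAM/BAM template lengths or a TSV histogram, with linear
  interpolation of unobserved lengths).
- **A seeded simulator** of fragmentation → uniform PCR (`2^cycles`) →
  sequencing (sampling without replacement), with exact uniform pattern
  sampling.
- **A transcript copy-number estimator**: the number of molecules behind an
  observed SPP, predicted by ECDF distance
  `Σ_i (E_m(x_i) − E_d(x_i))²(x_{i+1} − x_i)` to simulated references.
- A brute-force **oracle** that enumerates small pattern spaces and backs
  every recursion with exhaustive ground truth.

See `docs/methods.md` for the model's assumptions and numerical choices.

## Worked example

```python
from fragspace import (PatternSpaceModel, CoverageKind, count_patterns,
                       expected_profile, SimulationConfig, build_reference,
                       simulate_spp, estimate_molecules)

model = PatternSpaceModel(T=10, lengths=[4])
print(count_patterns(model))
# 7   <- seven maximal ways to tile 10 bp with 4 bp fragments (gaps < 4 bp)

spp = expected_profile(model, CoverageKind.START_POINT)
print(list(spp.values))
# [3, 2, 1, 1, 1, 2, 3, 0, 0, 0]   <- fragment starts per position, summed
#                                     over all 7 patterns (exact integers)

# Estimate how many molecules an observed profile came from:
big = PatternSpaceModel(T=1000, lengths=[100], read_length=100)
grid = [50, 150, 500, 1500, 5000]
ref = build_reference(SimulationConfig(big, M=50, S=20_000, seed=11), grid, n_rep=20)
test = simulate_spp(SimulationConfig(big, M=500, S=20_000, seed=900))
print(estimate_molecules(test, ref).predicted)
# 500   <- the grid point whose pooled reference ECDF is nearest the test ECDF
```

The `examples/` directory holds one narrative script per capability
(counting, profiles, weighting, simulation, estimation); each prints what it
computes and says what the numbers mean.  A thin CLI wraps the same
functions:

```bash
fragspace count -T 10 -F 4                                  # -> 7
fragspace profile -T 1000 -F 500 --kind start_point --out spp.tsv
fragspace weights hist.tsv -T 1000 --out-weights w.tsv
fragspace simulate -T 1000 -F 100 -M 500 --seed 7 --out run/
fragspace build-reference -T 1000 -F 100 --grid 50:5000:5 --out ref/
fragspace estimate --reference-dir ref/ --profile run/observed_start_point.tsv
```

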
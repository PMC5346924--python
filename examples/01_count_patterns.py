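"""Count exhaustive fragmentation patterns for a transcript.

A fragmentation pattern is one maximal placement of non-overlapping fragments
on the transcript: every gap left over is too short to hold another fragment.
The count FP(T, F) is exact (arbitrary-precision integer) and grows
exponentially with transcript length.
"""

from fragspace import PatternSpaceModel, count_patterns, enumerate_patterns

# Small space, checkable by hand: fragments of 4 bp on a 10 bp transcript.
small = PatternSpaceModel(T=10, lengths=[4])
print(f"FP(T=10, F=4) = {count_patterns(small)}")
for i, pattern in enumerate(enumerate_patterns(small), 1):
    print(f"  pattern {i}: {pattern.placements}")

# A range of fragment lengths: recursion iterates over lengths and gaps.
ranged = PatternSpaceModel(T=10, lengths=[3, 4])
print(f"FP(T=10, F=3..4) = {count_patterns(ranged)}")

# Realistic scale: the count is astronomically large but still exact.
big = PatternSpaceModel(T=1000, lengths=[100])
fp = count_patterns(big)
print(f"FP(T=1000, F=100) = {fp}  (~{float(fp):.3e})")

# FP(10,{4}) = 7: seven maximal ways to tile 10 bp with 4 bp fragments and
# gaps shorter than 4 bp.  The T=1000 count shows why full enumeration is
# infeasible and the recursion is needed.
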
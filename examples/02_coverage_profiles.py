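"""Expected coverage profiles: starting points, fragments, reads.

Summing each fragment's coverage vector over all (equally likely) patterns
gives the expected per-position profile.  Even without any experimental bias
these profiles are not uniform: peaks appear at spacings set by the fragment
length, and the fragment-to-transcript and read-to-fragment length ratios
control how pronounced they are.
"""

import numpy as np

from fragspace import CoverageKind, PatternSpaceModel, expected_profile

model = PatternSpaceModel(T=1000, lengths=[200], read_length=100)

spp = expected_profile(model, CoverageKind.START_POINT).normalize()
fcp = expected_profile(model, CoverageKind.FRAGMENT).normalize()
rcp = expected_profile(model, CoverageKind.READ).normalize()

for name, prof in [("SPP", spp), ("FCP", fcp), ("RCP", rcp)]:
    vals = prof.as_float()
    print(f"{name}: min={vals.min():.2e}  max={vals.max():.2e}  "
          f"peak-to-valley={vals.max() / vals[vals > 0].min():.2f}")

# With R/F = 0.5 both read ends together tile the whole fragment, so the read
# profile coincides with the fragment profile:
print("RCP == FCP at R/F = 0.5:",
      np.array_equal(rcp.as_float(), fcp.as_float()))

# For F/T > 0.5 every feasible starting position is equally likely:
wide = expected_profile(PatternSpaceModel(1000, [700]),
                        CoverageKind.START_POINT).normalize().as_float()
print("SPP uniform over potential starts (F=700):",
      np.unique(wide[:301]).size == 1, "| zero beyond:", np.all(wide[301:] == 0))
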
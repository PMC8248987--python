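"""Test conditions for a concerted directional shift in intron excision.

Builds a delta-PSI table for 12 conditions where the first two have a strong
bias toward positive excision changes, then runs the exact binomial test.
The null proportion p0 is the average positive fraction over all conditions,
so the test asks whether a condition deviates from the global tendency —
with many shifted conditions the unshifted ones would start to look like
negative shifts, which is why the comparison set matters.
"""

import casekit as ck

psi = ck.simulate_psi_table(n_conditions=12, n_introns=300,
                            shift=[0.25, 0.25] + [0.0] * 10, seed=41)
result = ck.direction_test(psi, fdr_level=0.10)
print(result[["condition", "n_pos", "n_tested", "p0", "p", "q",
              "significant", "direction"]].to_string(index=False))
# The two shifted conditions show strong positive shifts (q << 0.10).  Note
# that because p0 is itself pulled upward by the shifted conditions, some
# unshifted conditions can cross the threshold with negative direction: the
# test is relative to the global tendency, not to an absolute 50:50 split.
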
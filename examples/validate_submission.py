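"""Catch a flipped-microstate submission error.

Reproduces, with synthetic energies, the bookkeeping error class where two
microstates' free energies are exchanged in a submitted file: recomputing
the macroscopic pKa from the corrupted table disagrees with the reported
value and the validator flags it.
"""

from logpka import validate_microstate_table
from logpka.synthetic import flipped_microstate_scenario

# relative-transition dialect: the proton term is folded into the values
correct, corrupted, reported = flipped_microstate_scenario(discrepancy=3.90)

for label, ms in (("correct file", correct), ("flipped file", corrupted)):
    report = validate_microstate_table(ms, reported, tol=0.10, proton=None)
    status = "FLAGGED" if report.flagged else "consistent"
    print(f"{label}: recomputed {report.recomputed_macro_pka:.2f} vs "
          f"reported {report.reported_macro_pka:.2f} "
          f"(discrepancy {report.discrepancy:+.2f}) -> {status}")
# A cross-charge flip moves the recomputed macroscopic pKa by twice the
# energy gap in pKa units; within-charge flips are invisible because the
# charge-state partition sum is permutation-invariant.
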
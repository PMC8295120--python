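"""Macroscopic pKa aggregated over tautomeric microstates.

A compound with one neutral form and two anionic tautomers: the observable
pKa pools both anions' partition functions, so it sits below the most acidic
microscopic pKa by up to log10(number of tautomers).
"""

from logpka import Microstate, MicrostateSet, ProtonParameters, macro_pka

proton = ProtonParameters()  # G_aq(H+) = -270.29 kcal/mol

ms = MicrostateSet(
    "demo",
    [
        Microstate("demo_micro001", "demo", 0, [-30.0, -29.4]),   # neutral acid HX
        Microstate("demo_micro002", "demo", -1, [250.2]),          # anion tautomer 1
        Microstate("demo_micro003", "demo", -1, [250.9, 251.0]),   # anion tautomer 2
    ],
)

res = macro_pka(ms, acid_charge=0, proton=proton)
print(f"macroscopic pKa = {res.macro_pka:.3f}")
for (acid_id, base_id), value in sorted(res.micro_pkas.items()):
    print(f"  micro pKa {acid_id} -> {base_id}: {value:.3f}")
# The macroscopic value lies below the smallest microscopic pKa because the
# deprotonated side gains tautomeric (and conformational) entropy.
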
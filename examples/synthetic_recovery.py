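"""Ground-truth recovery on a synthetic free-energy dataset.

Generates conformer and microstate tables with exactly embedded log P and
pKa targets, runs the full pipeline, and reports the recovery error —
zero to machine precision without noise, and growing with the per-component
noise level.
"""

import numpy as np

from logpka import ProtonParameters, compound_logp, macro_pka
from logpka.io import ensembles_from_dataframe, microstate_sets_from_dataframe
from logpka.synthetic import SyntheticSpec, generate

proton = ProtonParameters()

for noise in (0.0, 0.5):
    ds = generate(SyntheticSpec(n_compounds=100, seed=7, energy_noise_sd=noise))
    logp_err = np.array([
        compound_logp(e).logp - ds.ground_truth.true_logp[e.compound_id]
        for e in ensembles_from_dataframe(ds.conformer_table)
    ])
    pka_err = np.array([
        macro_pka(m, 0, proton).macro_pka
        - ds.ground_truth.true_macro_pka[m.compound_id]
        for m in microstate_sets_from_dataframe(ds.microstate_table, "absolute_aqueous")
    ])
    print(f"noise sd = {noise:.1f} kcal/mol:  "
          f"log P rmsd = {np.sqrt(np.mean(logp_err**2)):.4f},  "
          f"pKa rmsd = {np.sqrt(np.mean(pka_err**2)):.4f}")
# At 0.5 kcal/mol per free-energy component the log P error is ~0.75 log
# units (roughly sqrt(4)*sd / RTln10): free-energy noise converts to
# property error through the 1.364 kcal/mol-per-log-unit scale.
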
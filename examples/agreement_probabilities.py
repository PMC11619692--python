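"""Why the tools flag the wrong pair: pairwise agreement probabilities.

Compares P(T_i = T_j) under the dependence model ('observed', exact) with
the same parameters stripped of the covariance ('true CInd') for two
scenarios. In HHHH-HHHH the dependence makes T1xT2 the *highest* agreement,
which the misspecified independence fit then chases; in LLHH-LLHH the most
accurate pair T3xT4 dominates anyway and the fit stays honest.
"""

import lcmgof as m

scenarios = [
    m.scenario_from_codes("HHHH", "HHHH", prevalence=0.5, omega=0.5, n_obs=2000),
    m.scenario_from_codes("LLHH", "LLHH", prevalence=0.5, omega=0.5, n_obs=2000),
]
table = m.run_agreement_table(scenarios)
print(table.round(3).to_string(index=False))
# 'observed' and 'true_cind' differ only for T1xT2 - the dependence raises
# that pair's agreement (0.865 vs 0.82, and 0.64 vs 0.52).
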
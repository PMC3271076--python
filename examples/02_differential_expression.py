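"""Rank-product differential expression on a simulated probe matrix.

Simulates a growth-medium (GM) vs differentiation-medium (DM, day 3) probe
intensity matrix with 10% of probes planted up- and 10% down-regulated at
fold change 4, then normalizes, ranks by the rank-product statistic and
selects the regulated sets at the published thresholds (fold change > 2,
permutation p <= 0.05).
"""

import mircircuit as mc

config = mc.SyntheticStudyConfig(n_mirnas=200, n_probes=200, n_target_mirnas=20, rng_seed=4)
matrix, truth = mc.simulate_expression(config, targets=[])

results = mc.differential_expression(matrix, n_perm=500, seed=4)
up, down = mc.select_regulated(results)

print(results.table.sort_values("rank").head(5)[["fold_change", "rp_up", "p_up", "rank"]])
print(f"\nselected: {len(up)} up, {len(down)} down (planted 20 + 20)")
planted_up = set(truth.index[truth.regulation == "up"])
print(f"planted up-probes recovered: {len(planted_up & set(up))}/{len(planted_up)}")
# The table head shows the strongest up-regulated probes: rank-product RP near 1
# means the probe was among the most up-regulated in every replicate pair.
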
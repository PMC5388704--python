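"""Simulate a two-group cohort and compare kinetic energy between groups.

Draws per-subject peak systolic/diastolic KE/SV from the Fontan-LV and
control-LV reference distributions, runs the full measurement chain on
every subject, tabulates mean +/- SD per group, and applies the exact
Mann-Whitney test (suppressed automatically for subgroups below n = 5).
"""

import ke4dflow as k

cfg = k.CohortRunConfig(seed=12, out_dir="scratch/example_cohort",
                        n_per_group=8)
result = k.run_cohort(cfg)

table = result["table"]
for metric in ("peak_systolic_ke_sv", "peak_diastolic_ke_sv", "ef"):
    for _, row in table[table.metric == metric].iterrows():
        print(f"{metric:>22} {row.group:>8}: "
              f"{row['mean']:.4g} +/- {row.sd:.2g}  (n={row.n})")

for metric, test in result["tests"].items():
    if test["suppressed"]:
        print(f"{metric}: comparison suppressed ({test['reason']})")
    else:
        print(f"{metric}: Mann-Whitney U={test['U']:.0f}, "
              f"p={test['p_value']:.4g} ({'exact' if test['exact'] else 'approx'})")
# With 8 per group the diastolic KE/SV difference between the groups is
# large (0.033 vs 0.058 mJ/ml by construction) and the exact test finds it.
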
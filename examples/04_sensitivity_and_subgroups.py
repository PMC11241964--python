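"""Sensitivity definitions, age subgroups, and the concomitant outcome.

Three robustness views of the same database: alternative composite
definitions of delirium (nested around the primary one), the analysis
repeated within age bands 65-74 and 75+, and the rarer joint outcome
"delirium with hyponatraemia" that isolates the hyponatremia pathway.
"""

import pvsignal as pv
from pvsignal.config import StudyConfig

config = StudyConfig()
reports, _ = pv.generate_reports(pv.preset_scenario("study_like", n_reports=20_000, seed=11))

sens = pv.run_sensitivity(reports, config)
print("sensitivity analyses (signal status per definition):")
for aid, group in sens.groupby("analysis_id"):
    statuses = {r.exposure: r.signal for r in group.itertuples()}
    n_cases = int(group.iloc[0]["a"] + group.iloc[0]["b"])
    print(f"  {aid:<16} cases={n_cases:<5} {statuses}")
print("  concordant with primary:", int(sens["concordant_with_primary"].sum()), "/", len(sens))

ages = pv.run_age_subgroups(reports, config)
print("\nage subgroups (adjusted r-OR):")
for row in ages.itertuples():
    print(f"  {row.analysis_id:<12} {row.exposure:<7} {row.ror_adj:6.2f} {row.signal}")

conco = pv.run_concomitant(reports, config)
print("\nconcomitant delirium + hyponatraemia (SSRIs carry the pathway):")
for row in conco.itertuples():
    flag = f" ({row.flags})" if row.flags else ""
    adj = f"{row.ror_adj:.2f}" if row.ror_adj == row.ror_adj else "n/a"
    print(f"  {row.exposure:<7} a={row.a:<3} adjusted={adj} {row.signal}{flag}")
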
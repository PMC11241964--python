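"""Override the study configuration from YAML.

Everything the pipeline assumes — event definitions, class membership,
confounder dictionary, thresholds — is data, not code.  This example
narrows the primary definition, adds a confounder, and lowers the
frequent-drug threshold for a desk-scale dataset.
"""

import tempfile
from pathlib import Path

import pvsignal as pv

YAML = """
event_definitions:
  primary: [Delirium, "Confusional state"]
confounders:
  - {label: age_band, kind: demographic, matcher: age_band}
  - {label: sex, kind: demographic, matcher: sex}
  - {label: region, kind: demographic, matcher: region}
  - {label: opioids, kind: drug_atc, matcher: N02}
  - {label: dementia, kind: event_pt, matcher: Dementia}
frequent_drug_threshold: 150
seed: 9
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "study.yaml"
    path.write_text(YAML)
    config = pv.load_study_config(path)

print("primary definition:", sorted(config.definition("primary").terms))
print("confounders:", [c.label for c in config.confounders])
print("frequent-drug threshold:", config.frequent_drug_threshold)

reports, _ = pv.generate_reports(pv.preset_scenario("study_like", n_reports=10_000, seed=9))
per_drug = pv.run_per_drug(reports, config)
print("\nper-drug analysis (drugs in more than 150 reports):")
for row in per_drug.itertuples():
    print(
        f"  {row.analysis_id:<16} {row.exposure:<13} "
        f"adjusted {row.ror_adj:.2f} [{row.ror_adj_low:.2f}-{row.ror_adj_high:.2f}] {row.signal}"
    )
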
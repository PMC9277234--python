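"""Classify significant variants into pleiotropy categories and sign labels:
concordant (fitness alignment) vs discordant (fitness conflict)."""

import json
import shutil

import pandas as pd

from common import RESULTS, RUN_DIR, runner

r = runner()
r.run(only=["simulate", "poolfit", "means", "gwas", "permute", "pleiotropy"])

rec = pd.read_csv(RUN_DIR / "pleiotropy_records.tsv", sep="\t", comment="#")
summ = pd.read_csv(RUN_DIR / "concordance_summary.tsv", sep="\t", comment="#")
overlap = json.loads((RUN_DIR / "host_overlap.json").read_text())
print(f"pleiotropic variants detected: {rec.site_id.nunique()}")
if len(rec):
    print(rec.to_string(index=False))
print("\nhost overlap:", overlap["dza_only"], "DZA-only,",
      overlap["a17_only"], "A17-only,", overlap["shared"], "shared")
shutil.copy(RUN_DIR / "concordance_summary.tsv", RESULTS / "concordance_summary.tsv")
shutil.copy(RUN_DIR / "host_overlap.json", RESULTS / "host_overlap.json")
shutil.copy(RUN_DIR / "pleiotropy_records.tsv", RESULTS / "pleiotropy_records.tsv")
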
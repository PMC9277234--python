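"""Permutation-based family-wise significance thresholds per GWAS run."""

import json
import shutil

from common import RESULTS, RUN_DIR, runner

r = runner()
r.run(only=["simulate", "poolfit", "means", "gwas", "permute"])

thresholds = json.loads((RUN_DIR / "thresholds.json").read_text())
print("family-wise |beta| thresholds (alpha = 0.05, B = 1000 permutations):")
for key, t in sorted(thresholds.items()):
    print(f"  {t['trait']:>18s} on {t['host']}: |beta| >= {t['threshold_beta']:.3f}")
shutil.copy(RUN_DIR / "thresholds.json", RESULTS / "thresholds.json")
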
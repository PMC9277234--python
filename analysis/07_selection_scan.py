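"""Per-gene diversity/neutrality statistics and the comparison of pleiotropy
gene categories against all genes containing significant variants."""

import json
import shutil

import pandas as pd

from common import RESULTS, RUN_DIR, runner

r = runner()
r.run()  # full chain

stats = pd.read_csv(RUN_DIR / "gene_stats.tsv", sep="\t", comment="#")
print(f"gene statistics computed for {len(stats)} genes; "
      f"mean pi/site = {stats.pi_per_site.mean():.4f}, "
      f"mean Tajima's D = {stats.tajima_d.mean():.3f}")
comps = json.loads((RUN_DIR / "category_comparisons.json").read_text())
if comps:
    print("category vs null-pool comparisons:")
    for c in comps:
        flag = "significant" if c["significant"] else "ns"
        print(f"  {c['focal_category']:>40s} {c['statistic']:>14s}: "
              f"focal mean {c['focal_mean']:+.3f} vs null {c['null_grand_mean']:+.3f} "
              f"(p = {c['p_value']:.3f}, {flag})")
else:
    print("no category comparisons possible (no pleiotropic genes detected)")
shutil.copy(RUN_DIR / "category_comparisons.json", RESULTS / "category_comparisons.json")
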
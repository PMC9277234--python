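"""Rack-corrected estimated marginal means per strain and the pairwise
phenotypic correlations between fitness proxies on each host line."""

import shutil

import pandas as pd

from common import RESULTS, RUN_DIR, runner

r = runner()
r.run(only=["simulate", "poolfit", "means"])

corr = pd.read_csv(RUN_DIR / "correlations.tsv", sep="\t", comment="#")
print("phenotypic correlations (Pearson r of per-strain summaries):")
print(corr[["host", "trait_x", "trait_y", "r", "p", "n", "stars"]].to_string(index=False))
shutil.copy(RUN_DIR / "correlations.tsv", RESULTS / "phenotypic_correlations.tsv")
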
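"""Reconstruct strain frequencies from pooled nodule sequencing and derive
fold-change relative fitness per strain and host."""

import shutil

import pandas as pd

from common import RESULTS, RUN_DIR, runner

r = runner()
r.run(only=["simulate", "poolfit"])

diag = pd.read_csv(RUN_DIR / "pool_diagnostics.tsv", sep="\t", comment="#")
fit = pd.read_csv(RUN_DIR / "relative_fitness.tsv", sep="\t", comment="#")
print("reconstruction diagnostics (weighted MSE residual per pool):")
print(diag.to_string(index=False))
print(f"\nrelative fitness summarized for {fit.strain.nunique()} strains; "
      f"log2 fold-change range [{fit.log2_fold_change.min():.2f}, {fit.log2_fold_change.max():.2f}]")
shutil.copy(RUN_DIR / "relative_fitness.tsv", RESULTS / "relative_fitness.tsv")
shutil.copy(RUN_DIR / "pool_diagnostics.tsv", RESULTS / "pool_diagnostics.tsv")
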
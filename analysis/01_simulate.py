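"""Generate the synthetic study: strain panel, genes, phenotypes, pools.

Emulates a rhizobium panel experiment — 100 haploid strains in 4
subpopulations genotyped at 5000 sites across three replicons, replicate
single-strain phenotypes on two host lines with rack effects, and a
multi-strain pooled-sequencing experiment — with six planted pleiotropic
variants (3 concordant, 3 discordant) recorded in a truth ledger.
"""

import pandas as pd

from common import RUN_DIR, runner

r = runner()
r.run(only=["simulate"])

phen = pd.read_csv(RUN_DIR / "phenotypes.csv")
print(f"panel written to {RUN_DIR}")
print(f"replicate phenotype rows: {len(phen)} "
      f"({phen.strain.nunique()} strains x {phen.trait.nunique()} traits x 2 hosts)")
import json
truth = json.loads((RUN_DIR / "truth.json").read_text())
causal = pd.DataFrame(truth["causal"])
print("planted causal variants:")
print(causal.drop_duplicates(["pair_id", "host"])[["pair_id", "site_id", "host", "label", "category"]]
      .to_string(index=False))
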
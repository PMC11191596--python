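"""Full multi-site budget on a synthetic archipelago.

Generates an 11-site archipelago (4 oxic, 3 hypoxic, 4 euxinic water
columns), runs the complete per-site chain (benthic flux, SMTZ, redox,
sea-air flux, removal efficiency) and prints the budget table plus the
cross-site SMTZ/flux rank correlations.
"""

import pandas as pd

from coastalch4.budget import flux_vs_smtz
from coastalch4.pipeline import run_archipelago

budgets = run_archipelago(n_sites=11, seed=7)
table = pd.DataFrame([b.report_row() for b in budgets])
print(table.round(3).to_string(index=False))

rho_b, n = flux_vs_smtz(budgets, "benthic")
rho_a, _ = flux_vs_smtz(budgets, "sea_air")
print(f"\nSpearman rho (SMTZ depth vs benthic flux)  = {rho_b:.3f}  (n = {n})")
print(f"Spearman rho (SMTZ depth vs sea-air flux)  = {rho_a:.3f}")
# Both correlations are negative: the shallower the SMTZ, the larger the
# benthic release and the atmospheric emission, with euxinic shallow-SMTZ
# sites at the top of the emission ranking.
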
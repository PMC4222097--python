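"""Meta-analysis hygiene filters on a merged ratio table.

Builds a small merged table (one gene per filtering scenario, eight
studies) and applies the standard thresholds: group N >= 5, gene covered
by >= 5 studies, and >= 75% of contributing studies agreeing on the
direction of regulation.
"""

import numpy as np
import pandas as pd

from arraymeta.merge import ColumnMeta, FilterConfig, MergedTable, apply_filters

patterns = {
    "CONSISTENT_UP":  [1, 1, 1, 1, 1, 1, 1, 1],
    "AGREE_75PCT":    [1, 1, 1, 1, 1, 1, -1, -1],   # exactly 75% up
    "AGREE_62PCT":    [1, 1, 1, 1, 1, -1, -1, -1],  # 62.5% < 75%
    "ONLY_4_STUDIES": [1, 1, 1, 1, None, None, None, None],
    "SPLIT_DOWN":     [-1, 1, -1, 1, -1, 1, -1, -1],
}
columns = [ColumnMeta(s, "disease", n_group=8, n_control=8) for s in range(1, 9)]
values = pd.DataFrame(
    [[np.nan if v is None else float(v) * 0.8 for v in row] for row in patterns.values()],
    index=pd.Index(list(patterns), name="Gene"),
    columns=[c.label for c in columns],
)
table = MergedTable(columns=columns, values=values)

config = FilterConfig(min_group_n=5, min_studies_per_gene=5, min_direction_agreement=0.75)
kept = apply_filters(table, config)

print(f"before: {len(table.genes)} genes;  after: {len(kept.genes)} genes")
for gene in table.genes:
    status = "kept" if gene in kept.genes else "dropped"
    print(f"  {gene:15s} {status}")
print("\n(75% agreement is the inclusive boundary; genes in fewer than five")
print(" studies or without a 75% direction majority are removed)")
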
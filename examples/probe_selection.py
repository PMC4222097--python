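"""Collapsing multi-probe genes: suffix priority, then control brightness.

Affymetrix-style probe names encode specificity in their ending ("_at" is
gene-specific, "_s_at" cross-hybridizes within a family, "_x_at" is
promiscuous).  Given an ordered suffix whitelist, probes are ranked by the
longest matching ending; among equally ranked probes the one with the
highest mean (or median) control-group intensity wins.
"""

import numpy as np

from arraymeta.refinement import Center, probe_priority, select_probe

suffixes = ["_at", "_s_at", "_x_at"]
for probe in ["1001_at", "1001_s_at", "1001_x_at", "AFFX-ctrl"]:
    rank = probe_priority(probe, suffixes)
    print(f"{probe:12s} -> rank {rank if rank is not None else 'EXCLUDED'}")

print()
candidates = [
    ("207625_s_at", np.array([7.9, 8.1, 8.0])),   # rank 1, bright
    ("204338_at",   np.array([5.0, 5.2, 5.1])),   # rank 0, dim
    ("216965_at",   np.array([6.8, 7.0, 6.9])),   # rank 0, brighter
]
chosen = select_probe(candidates, suffixes, Center.MEAN)
print(f"selected probe: {chosen}")
print("(both '_at' probes outrank the brighter '_s_at'; among them the one")
print(" with the higher control mean, 216965_at at 6.9 vs 5.1, is chosen)")
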
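"""Reproduce the published biomarker panel from the packaged reference table.

The package ships the per-pathway pre-flight/in-flight correlation values
reported for the ten-astronaut study (E-GEOD-74708).  This script classifies
each pair's correlation transition, applies the panel screen (|ΔCC| >= 0.70
plus a decisive strength-class flip), and prints the per-pathway selected
counts and the pooled gene panel.
"""

from deltacc import reference_pair_correlations
from deltacc.panel import pairs_from_table, panel_genes, select_panel

table = reference_pair_correlations()
pooled = []
print("pathway block                              selected / screened")
for name, grp in table.groupby("pathway", sort=False):
    pairs = pairs_from_table(grp)
    selected = select_panel(pairs)
    pooled.extend(selected)
    print(f"{name:<42} {len(selected):>8} / {len(pairs)}")

seen = set()
unique = [p for p in pooled if not (p.pair_id in seen or seen.add(p.pair_id))]
genes = panel_genes(unique)
print(f"\n{len(unique)} distinct selected pairs -> panel of {len(genes)} genes:")
print(", ".join(genes))
print(
    "\nEach selected pair lost (or gained) a strong co-expression "
    "relationship in flight; the gene union is the proposed monitoring panel."
)
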
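"""Preprocess a reference/query pair and check marker recovery.

Doublet filtering, per-dataset expressed-gene matching, one-way-ANOVA
highly-variable-gene selection on the reference (Bonferroni-adjusted, lowest
adjusted p first), then total-count normalization + log1p.  Because the
simulation plants the marker genes, we can measure how many the ANOVA
selector recovers.
"""

from scmgcn import SimConfig, make_ref_query_pair, PreprocessConfig, preprocess_pair
from scmgcn.simulate import marker_gene_ids

cfg = SimConfig(n_types=4, n_genes=800, n_marker_per_type=40,
                n_ref_cells=300, n_query_cells=300, seed=0)
ref, query = make_ref_query_pair(cfg)

pre = PreprocessConfig(n_hvg=400, seed=0)
ref_p, query_p, hvg = preprocess_pair(ref, query, pre)

markers = set(marker_gene_ids(cfg))
recovered = len(markers & set(hvg))
print(f"kept {ref_p.n_cells}+{query_p.n_cells} cells after doublet filtering")
print(f"selected {len(hvg)} highly variable genes")
print(f"planted markers recovered in the selection: {recovered}/{len(markers)} "
      f"({recovered / len(markers):.0%})")
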
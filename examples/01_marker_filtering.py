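"""Marker filtering: MAF / missingness / heterozygosity, window thinning,
LD pruning, and random thinning.

Builds a small simulated within-species matrix and applies the standard
RADseq marker-filter cascade. The printed counts show how many markers each
step retains; the final set is what diversity and parentage analyses
consume.
"""

import dogwoodkin as dk
from dogwoodkin import benchmarks as bm

mat = bm.unrelated_benchmark(seed=7, n_accessions=80, n_markers=3000,
                             missing_rate=0.08)
print(f"simulated matrix: {mat.n_accessions} accessions x "
      f"{mat.n_markers} markers")

filtered = dk.filter_markers(mat, maf_min=0.05, missing_max=0.10,
                             het_max=0.90)
print(f"after MAF >= 0.05, missing <= 0.10, het <= 0.90: "
      f"{filtered.n_markers} markers")

thinned = dk.thin_by_window(filtered, window_bp=500)
print(f"after one-marker-per-500-bp thinning (highest heterozygosity "
      f"wins): {thinned.n_markers} markers")

pruned = dk.ld_prune(thinned, r2_max=0.5, window_markers=100)
print(f"after LD pruning at r^2 > 0.5 in 100-marker windows: "
      f"{pruned.n_markers} markers")

final = dk.random_thin(pruned, n_target=min(1000, pruned.n_markers), seed=1)
print(f"after random thinning: {final.n_markers} markers")
print("each step only removes markers; accessions are untouched.")
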
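"""Is classification difficulty a matter of ontology distance or of physical distance?

Uses the shuffled-layout atlas (region blocks placed at random on the
grid, so tree relatedness and physical adjacency are decoupled).
Pairwise AUROC rises with semantic (tree path) distance — closely related
regions are the hard ones — while the correlation with physical
(minimum inter-voxel Euclidean) distance is near zero.
"""

import argparse
import os

from atlasrep import (
    AtlasConfig,
    filter_dataset,
    pairwise_classify,
    simulate_paired_atlases,
    stratified_split,
    trend_by_distance,
    trend_by_path_length,
)
from atlasrep.replicability_analysis import region_pair_distances

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--lam", type=float, default=0.1)
parser.add_argument("--out", default="results/trends")
args = parser.parse_args()
os.makedirs(args.out, exist_ok=True)

cfg = AtlasConfig(seed=args.seed, layout="shuffled")
a, _, _ = simulate_paired_atlases(cfg)
a = filter_dataset(a)
mat = pairwise_classify(a, stratified_split(a, args.seed), lam=args.lam)

semantic = trend_by_path_length(mat, a.tree)
semantic.table.to_csv(f"{args.out}/trend_path_length.tsv", sep="\t", index=False)
print("mean AUROC by tree path length:")
for _, row in semantic.table.iterrows():
    print(f"  path {int(row['bin'])}: {row['mean_auroc']:.3f} "
          f"(sd {row['sd_auroc']:.3f}, n={int(row['n_pairs'])})")
print(f"Spearman(path length, AUROC) = {semantic.meta['spearman']:+.3f}")

distances = region_pair_distances(a, mat.regions, midline=cfg.midline)
physical = trend_by_distance(mat, distances)
physical.table.to_csv(f"{args.out}/trend_distance_deciles.tsv", sep="\t", index=False)
print(f"Pearson(physical distance, AUROC) = {physical.correlation:+.3f} "
      f"over {int(physical.table['n_pairs'].sum())} pairs")
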
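"""Within-dataset pairwise region classification and its chance control.

For each dataset: all-pairs LASSO classification (lambda 0.1) under the
stratified 50/50 two-fold scheme, the label-permutation control, and the
AUROC-based region dendrogram.  The headline finding is that leaf regions
are classifiable from expression alone in both datasets (mean AUROC near
1), more so in the low-rank dataset, while permuting labels collapses
performance to chance.
"""

import argparse
import os

import pandas as pd

from atlasrep import (
    AtlasConfig,
    auroc_region_clustering,
    filter_dataset,
    pairwise_classify,
    permutation_control,
    simulate_paired_atlases,
    stratified_split,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--lam", type=float, default=0.1)
parser.add_argument("--out", default="results/within")
args = parser.parse_args()
os.makedirs(args.out, exist_ok=True)

a, b, _ = simulate_paired_atlases(AtlasConfig(seed=args.seed))
for ds in (a, b):
    ds = filter_dataset(ds)
    folds = stratified_split(ds, seed=args.seed)
    mat = pairwise_classify(ds, folds, lam=args.lam)
    perm = permutation_control(ds, folds, lam=args.lam, seed=args.seed)
    mat.to_frame().to_csv(f"{args.out}/auroc_{ds.tag}.tsv", sep="\t")
    mat.pair_values().to_csv(f"{args.out}/auroc_{ds.tag}_pairs.tsv", sep="\t",
                             index=False)
    z, order = auroc_region_clustering(mat)
    pd.DataFrame(z, columns=["left", "right", "height", "size"]).to_csv(
        f"{args.out}/linkage_{ds.tag}.tsv", sep="\t", index=False
    )
    print(
        f"{ds.tag}: mean pairwise AUROC = {mat.summary_mean():.3f}, "
        f"permuted-label control = {perm.summary_mean():.3f}, "
        f"dendrogram leaf order starts {order[:3]}"
    )
print(f"matrices and linkage tables in {args.out}/")
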
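#!/usr/bin/env python
"""Alpha and beta diversity of each sample-type table by sanitary status.

Alpha diversity (Shannon, inverse Simpson) on relative abundances of the
retained genera, compared between HHS and LHS with a two-sided
Mann-Whitney U test. Beta diversity: Bray-Curtis dissimilarities, a
two-dimensional nonmetric MDS embedding (Kruskal stress-1), and a
one-way PERMANOVA (999 label permutations) on the ordination axes.
"""

from pathlib import Path

import pandas as pd

import farmbiome as fb
from farmbiome import io

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 37


def main() -> None:
    for sample_type in ("wall", "slat", "slurry"):
        d = RESULTS / "data" / sample_type
        counts = io.read_counts(d / "counts.tsv")
        meta = io.read_metadata(d / "metadata.tsv")
        filtered = fb.filter_sparse_genera(counts, meta)
        replaced = fb.replace_zeros(filtered)
        rel = replaced.div(replaced.sum(axis=1), axis=0)
        labels = meta.set_index("sample_id")["status"].loc[rel.index].to_numpy()

        per_sample, tests = fb.diversity_report(rel, meta)
        bc = fb.bray_curtis(rel)
        ordination = fb.nmds(bc, restarts=20, seed=SEED)
        f_stat, p_value = fb.permanova_on_axes(
            ordination.coordinates, labels, n_permutations=999, seed=SEED + 1
        )

        out = RESULTS / sample_type
        io.write_table(per_sample, out / "alpha_diversity.tsv")
        io.write_table(tests, out / "alpha_tests.tsv", index=False)
        io.write_table(bc, out / "bray_curtis.tsv")
        io.write_table(ordination.coordinates, out / "nmds_coords.tsv")
        beta = pd.DataFrame(
            [{"pseudo_F": f_stat, "p_value": p_value, "stress": ordination.stress}]
        )
        io.write_table(beta, out / "permanova.tsv", index=False)

        test_str = "; ".join(
            f"{r['index']} p={r['p_value']:.3f}" for _, r in tests.iterrows()
        )
        print(
            f"{sample_type}: alpha [{test_str}]; "
            f"NMDS stress {ordination.stress:.3f}; "
            f"PERMANOVA F={f_stat:.2f}, p={p_value:.3f}"
        )


if __name__ == "__main__":
    main()
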
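#!/usr/bin/env python
"""Differential expression across the heat-stress design: TMM
normalization, NB dispersion estimation, per-contrast GLM likelihood-ratio
tests with BH-FDR, plus library MDS, miRNA clustering and a heat map.

Reads results/mirna_counts.tsv and the sample sheet; writes one DE table
per contrast, MDS coordinates, the dendrogram and a heat map under
results/.
"""
import argparse
import json
from pathlib import Path

import pandas as pd

from hairpin2pare import diff_expression as de, pipeline, plots
from hairpin2pare.io_core import load_config, read_sample_sheet


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--config", default=None)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    cfg = load_config(args.config)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    counts = pd.read_csv(out / "mirna_counts.tsv", sep="\t", index_col="mirna")
    sheet = read_sample_sheet(Path(args.data) / "sample_sheet.tsv")

    results = de.run_de(counts, sheet, cfg["de"]["fdr"], cfg["de"]["prior_df"])
    sig_any = set()
    for name, res in results.items():
        pipeline.write_tsv(res, out / f"de_{name}.tsv")
        called = res.loc[res["significant"], "mirna"]
        sig_any.update(called)
        print(f"{name}: {len(called)} miRNAs at FDR < {cfg['de']['fdr']}")
    print(f"{len(sig_any)} distinct miRNAs differentially expressed in "
          f"at least one contrast")

    lg = de.log_rpm(counts)
    coords = de.mds_embed(lg.T.to_numpy())
    pipeline.write_tsv(
        pd.DataFrame({"library_id": lg.columns, "dim1": coords[:, 0],
                      "dim2": coords[:, 1]}),
        out / "mds_libraries.tsv",
    )
    if sig_any:
        sub = lg.loc[sorted(sig_any)]
        if len(sub) >= 2:
            merges = de.hcluster(sub.to_numpy())
            with open(out / "dendrogram_de_mirnas.json", "w") as fh:
                json.dump({"labels": list(sub.index), "merges": merges}, fh,
                          sort_keys=True)
            plots.heatmap(sub, out / "heatmap_de_mirnas.png",
                          title="differentially expressed miRNAs")
            print(f"heat map and dendrogram over {len(sub)} DE miRNAs written")


if __name__ == "__main__":
    main()
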
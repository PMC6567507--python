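#!/usr/bin/env python
"""Degradome (PARE) validation of miRNA-guided cleavage: map 19-21 nt
degradome tags to coding sequences, score miRNA target sites, test
cleavage-site peaks against dinucleotide-shuffled miRNAs, and keep targets
with p < 0.05 and cleavage-site abundance > 4.

Reads results/data/ and results/mirna_table.tsv; writes the target tables,
t-plot tables and example t-plot figures under results/, and compares the
retained set against the planted truth.
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from hairpin2pare import degradome as dg, pipeline, plots
from hairpin2pare.io_core import load_config, read_fasta


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--config", default=None)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    cfg = load_config(args.config)
    pcfg = cfg["pare"]
    data, out = Path(args.data), Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    transcripts = read_fasta(data / "transcripts.fa")
    tag_counts = dg.collapse_pare_tags(
        (s for _, s in read_fasta(data / "pare_tags.fa")),
        pcfg["min_len"], pcfg["max_len"],
    )
    mt = pd.read_csv(out / "mirna_table.tsv", sep="\t")
    mirnas = dict(zip(mt["name"], mt["sequence"]))
    rng = np.random.default_rng(np.random.SeedSequence([args.seed, 911]))

    hits = dg.find_targets(mirnas, transcripts, tag_counts, rng,
                           pcfg["score_threshold"], pcfg["n_shuffles"])
    profiles = dg.build_profiles(tag_counts, transcripts)
    retained, tplots = dg.filter_and_report(
        hits, profiles, pcfg["p_threshold"], pcfg["min_abundance"]
    )
    pipeline.write_tsv(hits, out / "targets_all.tsv")
    pipeline.write_tsv(retained, out / "targets_retained.tsv")
    tdir = out / "tplots"
    tdir.mkdir(parents=True, exist_ok=True)
    for key, table in sorted(tplots.items()):
        pipeline.write_tsv(table, tdir / f"{key.replace('@', '_')}.tsv")
    for row in retained.head(3).itertuples():
        plots.tplot(profiles[row.transcript_id], row.cleavage_pos,
                    tdir / f"{row.mirna}_{row.transcript_id}.png", row.mirna)

    print(f"{len(hits)} candidate sites (score <= {pcfg['score_threshold']}); "
          f"{len(retained)} retained at p < {pcfg['p_threshold']} and "
          f"abundance > {pcfg['min_abundance']}")
    truth_path = data / "truth_targets.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
        planted = truth[~truth.is_decoy]
        got_pos = {(r.transcript_id, r.cleavage_pos) for r in retained.itertuples()}
        hit = sum((r.transcript_id, r.cleavage_pos + 1) in got_pos
                  for r in planted.itertuples())
        print(f"planted cleavage sites recovered: {hit}/{len(planted)}; "
              f"decoy transcripts among retained: "
              f"{int(retained.transcript_id.str.startswith('decoy').sum())}")


if __name__ == "__main__":
    main()
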
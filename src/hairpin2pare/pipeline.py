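"""End-to-end orchestration of the analysis stages over synthetic or
user-supplied data. All tables are written deterministically (fixed float
format, sorted keys), so identical config + seed gives byte-identical
outputs.
"""
from __future__ import annotations

import json
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

from . import degradome, diff_expression, mirna_discovery, synthetic_data, tag_processing
from .io_core import RunManifest, read_fastq

FLOAT_FMT = "%.10g"


def write_tsv(df: pd.DataFrame, path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def collapse_libraries(
    read_source: dict[str, object],
    adapter: str,
    min_len: int = 18,
    max_len: int = 24,
    min_overlap: int = 7,
    manifest: RunManifest | None = None,
) -> pd.DataFrame:
    """Trim, size-select and collapse one library at a time (values of
    read_source are iterables of raw reads or FASTQ paths)."""
    counters: dict[str, Counter] = {}
    for lib, source in read_source.items():
        if isinstance(source, (str, Path)):
            reads = (seq for _, seq, _ in read_fastq(source))
        else:
            reads = source
        trimmed = tag_processing.trim_library(
            reads, adapter, min_overlap, manifest, stage=f"trim[{lib}]"
        )
        kept = tag_processing.size_select(
            trimmed, min_len, max_len, manifest, stage=f"size_select[{lib}]"
        )
        counters[lib] = Counter(kept)
    return tag_processing.collapse_counters(counters)


def discover(
    filtered_tags: pd.DataFrame,
    all_tag_seqs: set[str],
    genome: dict[str, str],
    config: dict,
    catalog=None,
    loci=None,
    manifest: RunManifest | None = None,
):
    """Mapping, candidate extraction, ascertainment, grouping, naming."""
    disc = config["discovery"]
    foldc = config["folding"]
    placements = mirna_discovery.map_tags_exact(filtered_tags.index, genome)
    abundance = {t: int(c) for t, c in filtered_tags.sum(axis=1).items()}
    mode = disc.get("mode", "auto")
    annotation = loci if (loci is not None and mode in ("auto", "annotation")) else None
    candidates = mirna_discovery.extract_precursor_windows(
        placements,
        genome,
        abundance,
        flanks=tuple(disc["flanks"]),
        threshold_per_nt=foldc["threshold_per_nt"],
        annotation=annotation,
        cluster_gap=disc["cluster_gap"],
        manifest=manifest,
    )
    mirnas = mirna_discovery.ascertain_mirnas(
        candidates, placements, filtered_tags, all_tag_seqs, catalog, manifest
    )
    mirna_discovery.name_mirnas(
        mirnas,
        candidates,
        catalog,
        disc["catalog_max_mismatches"],
        disc["catalog_max_len_diff"],
    )
    return mirnas, candidates


def run_all(config: dict, seed: int, out_dir, write_reads: bool = False) -> dict:
    """The full interlaced analysis on a synthetic dataset: simulate, tag
    processing, miRNA discovery, differential expression, degradome target
    validation. Writes all result tables under out_dir and returns the main
    objects for interactive use."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest()
    manifest.add("run", "seed", seed)

    ds = synthetic_data.simulate_dataset(config, seed)
    if write_reads:
        ds.write(out / "data")
    ds.sample_sheet.write(out / "sample_sheet.tsv")
    write_tsv(ds.truth_mirna, out / "truth_mirna.tsv")
    write_tsv(ds.truth_targets, out / "truth_targets.tsv")

    tags_cfg = config["tags"]
    sim_cfg = config["simulate"]
    tags = collapse_libraries(
        {l.library_id: ds.library_reads(l.library_id) for l in ds.sample_sheet},
        sim_cfg["adapter"],
        tags_cfg["min_len"],
        tags_cfg["max_len"],
        tags_cfg["min_overlap"],
        manifest,
    )
    filtered = tag_processing.rpm_filter(tags, tags_cfg["rpm_threshold"], manifest=manifest)
    write_tsv(filtered.reset_index(), out / "tags_filtered.tsv")

    mirnas, candidates = discover(
        filtered, set(tags.index), ds.genome, config, ds.catalog, ds.locus_bed, manifest
    )
    mtable = mirna_discovery.mirna_table(mirnas)
    write_tsv(mtable, out / "mirna_table.tsv")
    write_tsv(mirna_discovery.isomir_groups(mirnas), out / "isomir_groups.tsv")
    counts = mirna_discovery.mirna_counts(mirnas, filtered)
    write_tsv(counts.reset_index(), out / "mirna_counts.tsv")

    de_cfg = config["de"]
    de_results = {}
    if len(counts) >= 2:
        de_results = diff_expression.run_de(
            counts, ds.sample_sheet, de_cfg["fdr"], de_cfg["prior_df"]
        )
        for name, res in de_results.items():
            write_tsv(res, out / f"de_{name}.tsv")
        lg = diff_expression.log_rpm(counts)
        coords = diff_expression.mds_embed(lg.T.to_numpy())
        mds = pd.DataFrame(
            {"library_id": lg.columns, "dim1": coords[:, 0], "dim2": coords[:, 1]}
        )
        write_tsv(mds, out / "mds_libraries.tsv")
        if len(counts) >= 2:
            merges = diff_expression.hcluster(lg.to_numpy())
            with open(out / "dendrogram_mirnas.json", "w") as fh:
                json.dump(
                    {"labels": list(lg.index), "merges": merges}, fh, sort_keys=True
                )
                fh.write("\n")

    pare_cfg = config["pare"]
    pare_rng = np.random.default_rng(np.random.SeedSequence([seed, 911]))
    pare_counts = degradome.collapse_pare_tags(
        (s for _, s in ds.pare_tags), pare_cfg["min_len"], pare_cfg["max_len"]
    )
    manifest.add("pare", "tags_distinct", len(pare_counts))
    mir_for_pare = {
        m.name: m.sequence for m in mirnas
    } or ds.target_mirna_seqs()
    hits = degradome.find_targets(
        mir_for_pare,
        ds.transcripts,
        pare_counts,
        pare_rng,
        pare_cfg["score_threshold"],
        pare_cfg["n_shuffles"],
    )
    profiles = degradome.build_profiles(pare_counts, ds.transcripts)
    retained, tplots = degradome.filter_and_report(
        hits, profiles, pare_cfg["p_threshold"], pare_cfg["min_abundance"]
    )
    write_tsv(hits, out / "targets_all.tsv")
    write_tsv(retained, out / "targets_retained.tsv")
    tdir = out / "tplots"
    tdir.mkdir(exist_ok=True)
    for key, table in sorted(tplots.items()):
        write_tsv(table, tdir / f"{key.replace('@', '_')}.tsv")

    manifest.add("run", "mirnas", len(mirnas))
    manifest.add("run", "retained_targets", int(len(retained)))
    manifest.write(out / "manifest.json")
    return {
        "dataset": ds,
        "tags": tags,
        "filtered": filtered,
        "mirnas": mirnas,
        "candidates": candidates,
        "counts": counts,
        "de": de_results,
        "hits": hits,
        "retained": retained,
        "manifest": manifest,
    }
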
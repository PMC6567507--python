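"""On-disk formats, sample sheet, configuration and the run manifest.

Coordinates are 0-based half-open everywhere in memory; human-readable
reports render 1-based inclusive (``Chr1:101-180`` style).
"""
from __future__ import annotations

import copy
import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import yaml


class FormatError(ValueError):
    """A file violates its format contract (message names the location)."""


class ConfigError(RuntimeError):
    """Invalid or unusable configuration."""


VALID_TREATMENTS = ("control", "heat")
_SEQ_CHARS = set("ACGTUN")


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def _finish_record(path, header, parts, header_line, as_rna):
    seq = "".join(parts).upper()
    if not seq:
        raise FormatError(
            f"{path}: record '{header}' (line {header_line}) has an empty sequence"
        )
    bad = set(seq) - _SEQ_CHARS
    if bad:
        raise FormatError(
            f"{path}: record '{header}' contains invalid characters {sorted(bad)}"
        )
    seq = seq.replace("T", "U") if as_rna else seq.replace("U", "T")
    return header, seq


def read_fasta(path, as_rna: bool = False) -> list[tuple[str, str]]:
    """Read a (possibly gzipped) FASTA file.

    Record ids are the first whitespace-delimited token of the header.
    ``as_rna=True`` unifies T->U (RNA context); otherwise U->T (genomic
    context). N is retained; downstream exact mappers never match it.
    """
    records: list[tuple[str, str]] = []
    header = None
    header_line = 0
    parts: list[str] = []
    with _open_text(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append(_finish_record(path, header, parts, header_line, as_rna))
                tokens = line[1:].split()
                if not tokens:
                    raise FormatError(f"{path}: empty FASTA header at line {ln}")
                header, header_line, parts = tokens[0], ln, []
            else:
                if header is None:
                    raise FormatError(
                        f"{path}: sequence data before any '>' header at line {ln}"
                    )
                parts.append(line)
    if header is not None:
        records.append(_finish_record(path, header, parts, header_line, as_rna))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    with _open_text(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) from a 4-line-record FASTQ file.

    Gzip is transparent by extension. A truncated record or a quality string
    whose length differs from the sequence raises FormatError naming the
    record index (1-based).
    """
    with _open_text(path) as fh:
        idx = 0
        while True:
            head = fh.readline()
            if not head:
                return
            idx += 1
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise FormatError(f"{path}: truncated FASTQ record {idx}")
            head, seq, qual = head.strip(), seq.strip(), qual.strip()
            if not head.startswith("@"):
                raise FormatError(f"{path}: record {idx} does not start with '@'")
            if not plus.startswith("+"):
                raise FormatError(f"{path}: record {idx} missing '+' separator")
            if len(qual) != len(seq):
                raise FormatError(
                    f"{path}: record {idx} quality length {len(qual)} != sequence length {len(seq)}"
                )
            yield head[1:].split()[0], seq.upper(), qual


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    with _open_text(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Intervals, BED, GFF3
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def label(self) -> str:
        """1-based inclusive rendering for reports."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


def read_bed(path) -> list[tuple[GenomicInterval, str]]:
    """Read BED6 (name + strand used; score ignored) as (interval, name)."""
    out = []
    with _open_text(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {ln}: fewer than 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"region_{ln}"
            strand = fields[5] if len(fields) > 5 else "+"
            out.append((GenomicInterval(chrom, start, end, strand), name))
    return out


def write_bed(entries: Iterable[tuple[GenomicInterval, str]], path) -> None:
    with _open_text(path, "wt") as fh:
        for iv, name in entries:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_gff3(path) -> list[tuple[GenomicInterval, str]]:
    """Minimal GFF3 reader: returns (interval, ID attribute) per feature."""
    out = []
    with _open_text(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}: line {ln}: expected 9 GFF3 columns")
            chrom, _, _, start, end, _, strand, _, attrs = fields
            name = f"feature_{ln}"
            for part in attrs.split(";"):
                if part.startswith("ID="):
                    name = part[3:]
            strand = strand if strand in "+-" else "+"
            out.append((GenomicInterval(chrom, int(start) - 1, int(end), strand), name))
    return out


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Library:
    library_id: str
    treatment: str
    timepoint_days: int
    replicate: int
    file_path: str = ""


@dataclass
class SampleSheet:
    """The experimental design: libraries ordered by (treatment, timepoint,
    replicate). The default synthetic design is 2 treatments x 3 timepoints
    (0, 1, 4 days after treatment) x 4 replicates = 24 libraries."""

    libraries: list[Library] = field(default_factory=list)

    def __post_init__(self):
        ids = [l.library_id for l in self.libraries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate library_id(s): {dupes}")
        for lib in self.libraries:
            if lib.treatment not in VALID_TREATMENTS:
                raise FormatError(
                    f"library {lib.library_id}: unknown treatment {lib.treatment!r}"
                )
            if lib.replicate < 1:
                raise FormatError(f"library {lib.library_id}: replicate must be >= 1")
        self.libraries.sort(key=lambda l: (l.treatment, l.timepoint_days, l.replicate))

    def __len__(self):
        return len(self.libraries)

    def __iter__(self):
        return iter(self.libraries)

    @property
    def library_ids(self) -> list[str]:
        return [l.library_id for l in self.libraries]

    def cells(self) -> dict[tuple[str, int], list[str]]:
        out: dict[tuple[str, int], list[str]] = {}
        for lib in self.libraries:
            out.setdefault((lib.treatment, lib.timepoint_days), []).append(lib.library_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (l.library_id, l.treatment, l.timepoint_days, l.replicate, l.file_path)
                for l in self.libraries
            ],
            columns=["library_id", "treatment", "timepoint_days", "replicate", "file_path"],
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def default_design(
        cls,
        treatments=VALID_TREATMENTS,
        timepoints=(0, 1, 4),
        replicates: int = 4,
    ) -> "SampleSheet":
        libs = [
            Library(f"{t}_{tp}DAT_rep{r}", t, tp, r)
            for t in treatments
            for tp in timepoints
            for r in range(1, replicates + 1)
        ]
        return cls(libs)


def read_sample_sheet(path) -> SampleSheet:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty sample sheet") from None
    required = {"library_id", "treatment", "timepoint_days", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise FormatError(f"{path}: sample sheet has no rows")
    libs = [
        Library(
            str(r.library_id),
            str(r.treatment),
            int(r.timepoint_days),
            int(r.replicate),
            str(getattr(r, "file_path", "")),
        )
        for r in df.itertuples()
    ]
    return SampleSheet(libs)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "design": {"timepoints": [0, 1, 4], "replicates": 4},
    "simulate": {
        "n_precursors": 50,
        "n_decoys": 50,
        "depth": 200_000,
        "dispersion": 0.1,
        "background_fraction": 0.3,
        # documented TruSeq small-RNA 3' adapter
        "adapter": "TGGAATTCTCGGGTGCCAAGG",
        "read_length": 50,
        "mature_length_range": [20, 22],
        "loop_length": 8,
        "flank_length": 15,
        "stem_wobbles": 1,
        "max_isomirs": 3,
        "spacer_length": 1500,
        "n_chromosomes": 3,
        "rpm_total": 700_000.0,
        "base_rpm_range": [100.0, 30_000.0],
        "star_ratio_mean": 0.2,
        "de_fraction": 0.3,
        "min_abs_log2fc": 1.0,
        "timepoint_lfc_profile": [1.0, 0.5, 0.25],
        "catalog_fraction": 0.7,
        "pare": {
            "n_target_transcripts": 12,
            "n_decoy_transcripts": 6,
            "transcript_length": 500,
            "signal_mean": 50,
            "background_fraction": 0.5,
            "n_background_positions": 40,
        },
    },
    "tags": {"min_len": 18, "max_len": 24, "rpm_threshold": 10.0, "min_overlap": 7,
             "adapter_mismatches": 0},
    "folding": {"engine": "builtin", "threshold_per_nt": -0.2, "min_loop": 3},
    "discovery": {
        "flanks": [30, 60, 100, 150],
        "mode": "auto",  # annotation when precursor loci supplied, else denovo
        "cluster_gap": 15,
        "catalog_max_mismatches": 2,
        "catalog_max_len_diff": 2,
    },
    "de": {"fdr": 0.05, "prior_df": 10.0, "tmm_trim_m": 0.3, "tmm_trim_a": 0.05},
    "pare": {
        "min_len": 19,
        "max_len": 21,
        "score_threshold": 6.0,
        "n_shuffles": 100,
        "min_abundance": 4,
        "p_threshold": 0.05,
    },
}


def _deep_update(base: dict, other: dict) -> dict:
    for key, val in other.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], val)
        else:
            base[key] = val
    return base


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, overlaid with a YAML file, overlaid with explicit overrides
    (mirroring the CLI-overrides-config contract)."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with _open_text(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"{path}: top-level YAML must be a mapping")
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, overrides)
    return cfg


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

class RunManifest:
    """Structured per-stage counters (reads in/out at every filter)."""

    def __init__(self):
        self.stages: dict[str, dict] = {}

    def add(self, stage: str, key: str, value) -> None:
        self.stages.setdefault(stage, {})[key] = value

    def get(self, stage: str, key: str, default=None):
        return self.stages.get(stage, {}).get(key, default)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.stages, fh, indent=2, sort_keys=True)
            fh.write("\n")
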
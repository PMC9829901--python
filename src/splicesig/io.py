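"""Readers and writers for the pipeline's plain-text formats.

FASTA/FASTQ via Biopython (gzip transparent), SAM/BAM via pysam (in
``junction``), GMT gene sets, and schema-validated TSV tables (DGE results,
expression matrices, clinical records).  All TSVs are tab-separated with a
header row, UTF-8, '.' decimal.
"""

from __future__ import annotations

import gzip
import hashlib
import io as _io
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .junction import AlignmentParams, DetectionThresholds, JunctionCounts, SpliceTarget
from .signatures import GeneSignature, ImmunomodulatorSet
from .survival import validate_clinical

__all__ = [
    "FormatError",
    "open_text",
    "read_fasta",
    "read_fastq",
    "write_fastq",
    "read_gmt",
    "write_gmt",
    "read_immunomodulator_gmt",
    "read_dge_table",
    "read_expression",
    "read_clinical",
    "write_counts_tsv",
    "load_target",
    "PipelineConfig",
    "derive_seed",
]


class FormatError(ValueError):
    """A malformed record in an input file."""


def open_text(path: str | Path, mode: str = "rt"):
    """Open a possibly gzip-compressed text file."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """All (id, sequence) records of a FASTA file."""
    with open_text(path) as handle:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open_text(path, "wt") as handle:
        for name, seq in records:
            handle.write(f">{name}\n{seq}\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Stream (read_id, sequence, quality) tuples from a FASTQ file.

    Malformed records raise :class:`FormatError` naming the file and the
    0-based record index.
    """
    with open_text(path) as handle:
        it = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as err:
                raise FormatError(f"{path}: malformed FASTQ at record {index}: {err}") from err
            if len(seq) != len(qual):  # pragma: no cover - Biopython also checks
                raise FormatError(
                    f"{path}: record {index}: sequence and quality lengths differ")
            yield title.split()[0], seq.upper(), qual
            index += 1


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open_text(path, "wt") as handle:
        for read_id, seq, qual in reads:
            handle.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def load_target(fasta_path: str | Path, junction_start: int,
                excision_length: int = 26,
                transcript_id: str | None = None) -> SpliceTarget:
    """Build a :class:`SpliceTarget` from a single-record FASTA + junction."""
    records = read_fasta(fasta_path)
    if not records:
        raise FormatError(f"{fasta_path}: no FASTA records")
    if transcript_id is None:
        name, seq = records[0]
    else:
        match = [r for r in records if r[0] == transcript_id]
        if not match:
            raise FormatError(f"{fasta_path}: no record named {transcript_id!r}")
        name, seq = match[0]
    return SpliceTarget(transcript_id=name, sequence=seq,
                        junction_start=junction_start,
                        excision_length=excision_length)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Read gene sets from GMT (name <tab> description <tab> genes...)."""
    sigs = []
    with open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(g.strip() for g in parts[2:]):
                name = parts[0] if parts else f"line {lineno}"
                raise FormatError(f"{path}: gene set {name!r} has no genes (line {lineno})")
            genes = [g.strip() for g in parts[2:] if g.strip()]
            sigs.append(GeneSignature(name=parts[0], genes=genes, provenance="loaded"))
    return sigs


def write_gmt(signatures: Iterable[GeneSignature], path: str | Path,
              description: str | None = None) -> None:
    with open_text(path, "wt") as handle:
        for sig in signatures:
            desc = description if description is not None else sig.provenance
            handle.write("\t".join([sig.name, desc, *sig.genes]) + "\n")


def bundled_immunomodulator_db() -> list[ImmunomodulatorSet]:
    """The small synthetic illustrative immunomodulator pathway database.

    A stand-in for a manually curated literature database (which is manual
    work outside this package's scope): pathway names and member genes are
    plausible but synthetic, intended for demonstrations and tests of the
    overlap machinery only.
    """
    from importlib.resources import files

    path = files("splicesig").joinpath("data/immunomodulators_synthetic.gmt")
    return read_immunomodulator_gmt(str(path))


def read_immunomodulator_gmt(path: str | Path) -> list[ImmunomodulatorSet]:
    """GMT with metadata packed in the description as effect|species|organ|ref."""
    sets = []
    for sig in read_gmt(path):
        sets.append(ImmunomodulatorSet(name=sig.name, genes=sig.genes))
    # re-read descriptions for metadata
    out = []
    with open_text(path) as handle:
        for line, base in zip((l for l in handle if l.strip()), sets):
            desc = line.rstrip("\n").split("\t")[1]
            meta = (desc.split("|") + ["", "", "", ""])[:4]
            out.append(ImmunomodulatorSet(name=base.name, genes=base.genes,
                                          immune_effect=meta[0], species=meta[1],
                                          organ=meta[2], reference=meta[3]))
    return out


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_dge_table(path: str | Path) -> pd.DataFrame:
    """DGE results with columns gene, log2fc, pvalue, fdr."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene", "log2fc", "pvalue", "fdr") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: DGE table is missing columns {missing}")
    if df["gene"].duplicated().any():
        raise FormatError(f"{path}: DGE table has duplicate gene symbols")
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x samples abundance matrix (first column = gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise FormatError(f"{path}: expression matrix has duplicate gene symbols")
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: expression matrix has duplicate sample ids")
    if df.isna().any().any():
        raise FormatError(f"{path}: expression matrix has missing values")
    if (df.to_numpy(dtype=float) < 0).any():
        raise FormatError(f"{path}: expression values must be nonnegative")
    return df


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Clinical table: sample_id, time, event, then covariate columns."""
    df = pd.read_csv(path, sep="\t")
    try:
        return validate_clinical(df)
    except ValueError as err:
        raise FormatError(f"{path}: {err}") from err


def write_counts_tsv(counts: Sequence[JunctionCounts], path: str | Path) -> None:
    rows = []
    for c in counts:
        rows.append({
            "sample_id": c.sample_id,
            "spliced_count": c.spliced_count,
            "unspliced_count": c.unspliced_count,
            "uninformative_count": c.uninformative_count,
            "spliced_percent": "" if c.spliced_percent is None else f"{c.spliced_percent:.6g}",
            "pass_threshold": str(c.pass_threshold).lower(),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed below 2**31 from a global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    """End-to-end run configuration; round-trips losslessly through YAML."""

    # XBP1s quantification arm
    reads: str | None = None
    alignments: str | None = None
    reference: str | None = None
    junction_start: int | None = None
    excision_length: int = 26
    # signature arm
    dge_table: str | None = None
    signature_gmt: str | None = None
    expression: str | None = None
    clinical: str | None = None
    ortholog_map: str | None = None
    universe: str | None = None
    # parameters
    alignment: dict = field(default_factory=lambda: asdict(AlignmentParams()))
    thresholds: dict = field(default_factory=lambda: asdict(DetectionThresholds()))
    log2fc_min: float = 1.0
    fdr_max: float = 0.01
    p_max: float = 0.05
    ssgsea_alpha: float = 0.25
    ssgsea_normalize: bool = True
    stratify_mode: str = "tertile"
    cox_reference: str = "low"
    covariates: list = field(default_factory=list)
    n_random: int = 1000
    specificity_alpha: float = 0.05
    # bookkeeping
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})

    def content_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def alignment_params(self) -> AlignmentParams:
        return AlignmentParams(**self.alignment)

    def detection_thresholds(self) -> DetectionThresholds:
        return DetectionThresholds(**self.thresholds)
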
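"""Readers and writers for the standard formats the pipeline touches.

GTF parsing goes through gffutils and VCF reading through cyvcf2; the
writers emit the small synthetic fixtures (annotation, genotypes) and the
plain TSV matrices the pipeline exchanges.  Internally everything is
0-based half-open; GTF and VCF convert from/to 1-based at the boundary.
Missing values in TSV matrices are written as '.'.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .gene_model import (
    ExonicPart,
    GeneModel,
    Interval,
    Junction,
    TranscriptModel,
)

_STRAND_CODE = {"+": 1, "-": 2}
_CODE_STRAND = {0: "+", 1: "+", 2: "-"}  # STAR: 0 = undefined


# ---------------------------------------------------------------------------
# GTF


def _prevalidate_gtf(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated fields"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if end < start:
                raise ValueError(
                    f"{path}:{lineno}: end ({end}) < start ({start})"
                )


def read_gtf(path) -> list[GeneModel]:
    """Parse an Ensembl-dialect GTF into gene models.

    1-based closed exon coordinates become 0-based half-open; non-exon
    features are ignored; transcripts are grouped by gene_id.  Malformed
    lines are rejected with their line number."""
    path = Path(path)
    _prevalidate_gtf(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_gene: dict[str, dict] = {}
    for feat in db.all_features(featuretype="exon"):
        gene_id = feat.attributes["gene_id"][0]
        tx_id = feat.attributes["transcript_id"][0]
        entry = per_gene.setdefault(
            gene_id, {"chrom": feat.seqid, "strand": feat.strand, "tx": {}}
        )
        if entry["chrom"] != feat.seqid or entry["strand"] != feat.strand:
            raise ValueError(
                f"gene {gene_id}: transcripts on different chrom/strand"
            )
        entry["tx"].setdefault(tx_id, []).append((feat.start - 1, feat.end))
    genes = []
    for gene_id, entry in per_gene.items():
        transcripts = tuple(
            TranscriptModel(tx_id, tuple(sorted(exons)), entry["strand"])
            for tx_id, exons in entry["tx"].items()
        )
        genes.append(
            GeneModel(gene_id, entry["chrom"], entry["strand"], transcripts)
        )
    return genes


def write_gtf(gene: GeneModel, path) -> None:
    """Emit a gene model as Ensembl-dialect GTF (exon features only)."""
    lines = []
    for t in gene.transcripts:
        for start, end in t.exons:
            attrs = (
                f'gene_id "{gene.gene_id}"; transcript_id "{t.transcript_id}";'
            )
            lines.append(
                "\t".join(
                    [
                        gene.chrom,
                        "splicedose",
                        "exon",
                        str(start + 1),
                        str(end),
                        ".",
                        gene.strand,
                        ".",
                        attrs,
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED6


def parts_to_bed6(parts: Sequence[ExonicPart], chrom: str) -> str:
    """Exonic parts as BED6 text (0-based half-open; score 0)."""
    lines = [
        "\t".join(
            [chrom, str(p.interval[0]), str(p.interval[1]), p.part_id, "0", "+"]
        )
        for p in parts
    ]
    return "\n".join(lines) + "\n" if lines else ""


def intervals_to_bed6(
    intervals: Sequence[Interval], chrom: str, prefix: str = "intron"
) -> str:
    lines = [
        "\t".join([chrom, str(s), str(e), f"{prefix}:{i + 1}", "0", "+"])
        for i, (s, e) in enumerate(intervals)
    ]
    return "\n".join(lines) + "\n" if lines else ""


# ---------------------------------------------------------------------------
# VCF


def write_vcf(
    genotypes: pd.DataFrame,
    chrom: str,
    positions: Mapping[str, int],
    ref: Mapping[str, str],
    alt: Mapping[str, str],
    path,
) -> None:
    """Write diploid dosages (samples x SNPs, values 0/1/2 or NaN) as a
    minimal VCF 4.2 with GT fields."""
    samples = list(genotypes.index)
    header = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    records = []
    for snp_id in sorted(genotypes.columns, key=lambda s: positions[s]):
        calls = []
        for s in samples:
            dosage = genotypes.at[s, snp_id]
            calls.append(
                "./." if pd.isna(dosage) else gt_map[int(dosage)]
            )
        records.append(
            "\t".join(
                [
                    chrom,
                    str(positions[snp_id]),
                    snp_id,
                    ref[snp_id],
                    alt[snp_id],
                    ".",
                    "PASS",
                    ".",
                    "GT",
                ]
                + calls
            )
        )
    Path(path).write_text("\n".join(header + records) + "\n")


def read_vcf_dosages(
    path, snp_ids: Optional[Sequence[str]] = None
) -> dict[str, pd.Series]:
    """Extract per-sample ALT-allele dosage vectors from a VCF.

    Only biallelic SNP records are accepted for requested ids; ./. becomes
    NaN; sample order is preserved."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    wanted = set(snp_ids) if snp_ids is not None else None
    out: dict[str, pd.Series] = {}
    for variant in vcf:
        vid = variant.ID
        if vid is None or (wanted is not None and vid not in wanted):
            continue
        if len(variant.ALT) != 1:
            raise ValueError(f"variant {vid} is multiallelic")
        dosages = []
        for call in variant.genotypes:
            alleles = call[:-1]
            if any(a < 0 for a in alleles):
                dosages.append(np.nan)
            else:
                dosages.append(float(sum(1 for a in alleles if a == 1)))
        out[vid] = pd.Series(dosages, index=samples, name=vid)
    if wanted is not None:
        missing = wanted - set(out)
        if missing:
            raise KeyError(f"SNP id(s) not found in VCF: {sorted(missing)}")
    return out


# ---------------------------------------------------------------------------
# STAR SJ.out.tab-style junction tables


def write_sj_tab(
    junction_counts: Mapping[Junction, int], path, overhang: int = 6
) -> None:
    """Single-sample junction counts in STAR SJ.out.tab layout: chrom,
    1-based intron start/end, strand code, motif, annotated, unique count,
    multi-mapping count, max overhang."""
    lines = []
    for j in sorted(junction_counts, key=lambda j: (j.chrom, j.donor, j.acceptor)):
        lines.append(
            "\t".join(
                [
                    j.chrom,
                    str(j.donor + 1),
                    str(j.acceptor),
                    str(_STRAND_CODE[j.strand]),
                    "0",
                    "1",
                    str(int(junction_counts[j])),
                    "0",
                    str(overhang),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n" if lines else "")


def read_sj_tab(path) -> dict[Junction, int]:
    out: dict[Junction, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 7:
                raise ValueError(f"{path}:{lineno}: expected >= 7 fields")
            chrom = fields[0]
            start1, end1 = int(fields[1]), int(fields[2])
            strand = _CODE_STRAND[int(fields[3])]
            count = int(fields[6])
            out[Junction(chrom, start1 - 1, end1, strand)] = count
    return out


# ---------------------------------------------------------------------------
# TSV matrices


def write_matrix_tsv(frame: pd.DataFrame, path) -> None:
    frame = frame.copy()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t", na_rep=".")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["."])


# ---------------------------------------------------------------------------
# config and manifest


@dataclass
class PipelineConfig:
    """File paths and analysis options for a CLI run."""

    annotation: Optional[str] = None
    vcf: Optional[str] = None
    counts: Optional[str] = None
    covariates: Optional[str] = None
    out_dir: str = "."
    min_overhang: int = 6
    log1p: bool = False
    alpha: float = 0.05
    condition_on: Optional[str] = None
    seed: int = 1

    def __post_init__(self) -> None:
        if self.min_overhang < 1:
            raise ValueError("min_overhang must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def sha256_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    out_dir,
    config: Mapping,
    inputs: Iterable = (),
    seed: Optional[int] = None,
) -> Path:
    """Record tool version, config hash, input checksums, timestamp and
    seed — enough to reproduce the run."""
    from . import __version__

    config_json = json.dumps(dict(config), sort_keys=True, default=str)
    manifest = {
        "tool": "splicedose",
        "version": __version__,
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "inputs": {str(p): sha256_file(p) for p in inputs},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "seed": seed,
    }
    path = Path(out_dir) / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path
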
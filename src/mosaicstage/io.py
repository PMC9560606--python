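"""Standard-format input/output: VCF 4.2, BED, and the package's TSV tables.

Internal coordinates are 0-based half-open; VCF emission is 1-based.
Orientation-split alt read counts travel in two custom FORMAT fields.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .classify import ClassifiedVariant, IntervalTrack
from .core import Site, SiteAnnotation, TissueSample, VariantObservation
from .synthetic import GeneModel, TruthRecord

_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID={contig},length={length}>
##INFO=<ID=CTX,Number=1,Type=String,Description="Trinucleotide context on the genome plus strand">
##INFO=<ID=STR,Number=1,Type=String,Description="Strand of overlapping transcript">
##INFO=<ID=GENE,Number=1,Type=String,Description="Overlapping gene">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=F1R2,Number=1,Type=Integer,Description="Alt reads on F1R2 orientation">
##FORMAT=<ID=F2R1,Number=1,Type=Integer,Description="Alt reads on F2R1 orientation">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_tissue_vcf(
    path: Path,
    tissue: TissueSample,
    annotations: Optional[dict[Site, SiteAnnotation]] = None,
    contig_length: int = 10_000_000,
) -> None:
    sites = tissue.sites()
    contig = sites[0].contig if sites else "chr1"
    lines = [_VCF_HEADER.format(contig=contig, length=contig_length, sample=tissue.tissue_id)]
    for site in sites:
        obs = tissue.observations[site]
        info_parts = []
        ann = (annotations or {}).get(site)
        if ann is not None:
            info_parts.append(f"CTX={ann.context}")
            if ann.strand:
                info_parts.append(f"STR={ann.strand}")
            if ann.gene:
                info_parts.append(f"GENE={ann.gene}")
        info = ";".join(info_parts) or "."
        sample = (
            f"{obs.depth}:{obs.depth - obs.alt_count},{obs.alt_count}:"
            f"{obs.alt_f1r2}:{obs.alt_f2r1}"
        )
        lines.append(
            f"{site.contig}\t{site.pos + 1}\t.\t{site.ref}\t{site.alt}\t.\t.\t"
            f"{info}\tDP:AD:F1R2:F2R1\t{sample}\n"
        )
    Path(path).write_text("".join(lines))


def read_tissue_vcf(
    path: Path,
    individual: str,
    organ: str,
    age: float,
    is_tumor: bool = False,
) -> tuple[TissueSample, dict[Site, SiteAnnotation]]:
    """Parse one single-sample VCF back into a tissue with annotations."""
    tissue_id = None
    annotations: dict[Site, SiteAnnotation] = {}
    observations: dict[Site, VariantObservation] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                tissue_id = line.split("\t")[9]
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ValueError(f"{path}:{lineno}: truncated VCF record")
            contig, pos1, _, ref, alt, _, _, info, fmt, sample = fields[:10]
            site = Site(contig, int(pos1) - 1, ref, alt)
            info_map = dict(
                kv.split("=", 1) for kv in info.split(";") if "=" in kv
            )
            if "CTX" in info_map:
                annotations[site] = SiteAnnotation(
                    context=info_map["CTX"],
                    strand=info_map.get("STR"),
                    gene=info_map.get("GENE"),
                )
            values = dict(zip(fmt.split(":"), sample.split(":")))
            ad = values["AD"].split(",")
            observations[site] = VariantObservation(
                site=site,
                tissue_id=tissue_id or "",
                depth=int(values["DP"]),
                alt_count=int(ad[1]),
                alt_f1r2=int(values["F1R2"]),
                alt_f2r1=int(values["F2R1"]),
            )
    tissue = TissueSample(
        individual=individual,
        tissue_id=tissue_id or Path(path).stem,
        organ=organ,
        age=age,
        is_tumor=is_tumor,
        observations=observations,
    )
    return tissue, annotations


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(path: Path, intervals: Iterable[tuple[str, int, int]]) -> None:
    with open(path, "w") as fh:
        for contig, start, end in intervals:
            fh.write(f"{contig}\t{start}\t{end}\n")


def read_bed(path: Path) -> list[tuple[str, int, int]]:
    """Read a 3+ column BED file (0-based half-open)."""
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has < 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if end < start:
                raise ValueError(f"{path}:{lineno}: end before start")
            intervals.append((parts[0], start, end))
    return intervals


def load_blacklist_dir(directory: Path) -> dict[str, IntervalTrack]:
    tracks = {}
    for bed in sorted(Path(directory).glob("*.bed")):
        tracks[bed.stem] = IntervalTrack(read_bed(bed))
    return tracks


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def truth_to_frame(truth: list[TruthRecord]) -> pd.DataFrame:
    rows = []
    for rec in truth:
        rows.append(
            {
                "individual": rec.individual,
                "contig": rec.site.contig,
                "pos": rec.site.pos,
                "ref": rec.site.ref,
                "alt": rec.site.alt,
                "context": rec.annotation.context,
                "strand": rec.annotation.strand or ".",
                "gene": rec.annotation.gene or ".",
                "stage": rec.stage,
                "artifact_kind": rec.artifact_kind or ".",
                "artifact_tissue": rec.artifact_tissue or ".",
                "apparent_vaf": rec.apparent_vaf,
                "clone_vafs": ";".join(
                    f"{t}={v:.6g}" for t, v in sorted(rec.clone_vaf_by_tissue.items())
                ),
            }
        )
    return pd.DataFrame(rows)


def classified_to_frame(variants: list[ClassifiedVariant]) -> pd.DataFrame:
    rows = []
    for cv in variants:
        rows.append(
            {
                "individual": cv.individual,
                "contig": cv.site.contig,
                "pos": cv.site.pos,
                "ref": cv.site.ref,
                "alt": cv.site.alt,
                "stage": cv.stage,
                "organs": ";".join(sorted(cv.organs)) or ".",
                "mean_vaf": cv.mean_vaf,
                "anchor_tissue": cv.anchor_tissue,
                "presence_tissues": ";".join(cv.presence_tissues),
                "vafs": ";".join(
                    f"{t}={o.vaf:.6g}" for t, o in sorted(cv.observations.items())
                ),
                "p_values": ";".join(
                    f"{t}={d.p_value:.3g}" for t, d in sorted(cv.presence.items())
                ),
                "pass_primary": cv.pass_primary,
                "pass_secondary": cv.pass_secondary,
            }
        )
    return pd.DataFrame(rows)


def write_gene_models(path: Path, genes: list[GeneModel]) -> None:
    rows = [
        {
            "gene": g.gene,
            "contig": g.contig,
            "strand": g.strand,
            "cds_intervals": ",".join(f"{s}-{e}" for s, e in g.cds_intervals),
            "flank5": g.flank5,
            "flank3": g.flank3,
            "cds_seq": g.cds_seq,
            "protein": g.protein,
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_models(path: Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    genes = []
    for _, row in df.iterrows():
        intervals = [
            tuple(int(x) for x in part.split("-"))
            for part in str(row["cds_intervals"]).split(",")
        ]
        genes.append(
            GeneModel(
                gene=row["gene"],
                contig=row["contig"],
                strand=row["strand"],
                cds_intervals=intervals,
                cds_seq=row["cds_seq"],
                flank5=row["flank5"],
                flank3=row["flank3"],
                protein=row["protein"],
            )
        )
    return genes


def write_signature_matrix(path: Path, signatures: dict[str, np.ndarray]) -> None:
    from .core import CHANNELS_96

    df = pd.DataFrame(signatures, index=list(CHANNELS_96))
    df.index.name = "channel"
    df.to_csv(path, sep="\t")


def read_signature_matrix(path: Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col="channel")
    return {col: df[col].to_numpy(dtype=float) for col in df.columns}


def write_json(path: Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
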
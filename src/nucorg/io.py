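"""Readers and writers for the formats the pipeline touches.

GFF3 gene annotations are read through gffutils and converted to the
package's internal 0-based half-open coordinates; binding calls and
clusters are written as 6-column BED (0-based half-open); everything
tabular travels as TSV.  Output tables carry the pipeline config hash in
a leading comment line so printed numbers remain auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import gffutils
import pandas as pd
import yaml

from .chip import CALL_COLUMNS, PROBE_COLUMNS, BindingTrack, Cluster

logger = logging.getLogger(__name__)

__all__ = [
    "read_gff3",
    "write_gff3",
    "read_bed",
    "write_bed",
    "calls_to_bed",
    "clusters_to_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_spots",
    "read_probe_table",
    "read_expression",
    "write_table",
    "PipelineConfig",
]

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]
BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def _prevalidate_gff3(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ValueError(f"{path}: malformed GFF3 line {lineno}: {line[:60]!r}")


def read_gff3(path: str | Path, featuretype: str = "gene") -> pd.DataFrame:
    """Gene records (gene_id, chrom, start, end, strand), 0-based half-open.

    GFF3 coordinates are 1-based inclusive and converted on read.
    Strandless records are rejected.
    """
    path = Path(path)
    _prevalidate_gff3(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type(featuretype, order_by=("seqid", "start")):
        if feat.strand not in ("+", "-"):
            raise ValueError(f"{path}: feature {feat.id!r} has no strand")
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append(
            {
                "gene_id": gene_id,
                "chrom": feat.seqid,
                "start": feat.start - 1,  # to 0-based half-open
                "end": feat.end,
                "strand": feat.strand,
            }
        )
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def write_gff3(genes: pd.DataFrame, path: str | Path, source: str = "nucorg") -> None:
    """Write gene records back out as GFF3 (converting to 1-based inclusive)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.sort_values(["chrom", "start"]).iterrows():
            attrs = f"ID={g['gene_id']}"
            fh.write(
                f"{g['chrom']}\t{source}\tgene\t{g['start'] + 1}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\t{attrs}\n"
            )


def write_bed(intervals: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    """Standard 6-column BED, 0-based half-open, deterministically ordered.

    Unsorted input is sorted with a warning.  An empty table yields a
    file holding only the header comment.
    """
    missing = [c for c in BED_COLUMNS if c not in intervals.columns]
    if missing:
        raise ValueError(f"BED table missing columns: {missing}")
    df = intervals[BED_COLUMNS]
    if not df[["chrom", "start"]].equals(
        df[["chrom", "start"]].sort_values(["chrom", "start"], kind="mergesort")
    ):
        logger.warning("unsorted intervals passed to write_bed; sorting")
        df = df.sort_values(["chrom", "start"], kind="mergesort")
    with open(path, "w") as fh:
        fh.write(f"# {header or 'nucorg BED output'}\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=BED_COLUMNS,
        dtype={"chrom": str, "name": str, "strand": str},
    )
    return df


def calls_to_bed(track: BindingTrack, status: str = "positive") -> pd.DataFrame:
    """Binding calls of one status as BED rows; score = 100 x log2 ratio."""
    sub = track.calls[track.calls["status"] == status]
    return pd.DataFrame(
        {
            "chrom": sub["chrom"],
            "start": sub["start"],
            "end": sub["end"],
            "name": sub["locus_id"],
            "score": (sub["log2_ratio"] * 100).round().astype(int),
            "strand": ".",
        }
    ).reset_index(drop=True)


def clusters_to_bed(clusters: list[Cluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in clusters],
            "start": [c.start for c in clusters],
            "end": [c.end for c in clusters],
            "name": [f"{c.chrom}:{c.start}-{c.end}({c.n_loci})" for c in clusters],
            "score": [int(round(c.peak_log2 * 100)) for c in clusters],
            "strand": ["." for _ in clusters],
        }
    )


def read_chrom_sizes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["chrom", "length"])
    if (df["length"] <= 0).any():
        raise ValueError("chromosome lengths must be positive")
    return df


def write_chrom_sizes(sizes: pd.DataFrame, path: str | Path) -> None:
    sizes[["chrom", "length"]].to_csv(path, sep="\t", header=False, index=False)


def read_spots(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["cell_id", "stage", "distance_um", "diameter_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"spot table missing columns: {missing}")
    return df


def read_probe_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"probe table missing columns: {missing}")
    return df


def read_expression(values_path: str | Path, sample_map_path: str | Path):
    """Expression TSV (gene x sample) plus sample->strain map TSV."""
    from .expression import ExpressionMatrix

    values = pd.read_csv(values_path, sep="\t", comment="#", index_col=0)
    smap = pd.read_csv(sample_map_path, sep="\t", comment="#", header=None,
                       names=["sample", "strain"])
    return ExpressionMatrix(values=values, strains=dict(zip(smap["sample"], smap["strain"])))


def write_table(df: pd.DataFrame, path: str | Path, comment: str | None = None,
                index: bool = False) -> None:
    """TSV writer that prepends an auditable comment line."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=index)


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and sizes of the end-to-end demo pipeline.

    Thresholds default to the study's printed values: per-locus alpha
    0.025, expression alpha 0.05, 1.25-fold change, clusters of at least
    two loci with peak log2 > 0.8, 10-kb subtelomere zones, and a 9%
    random pore-colocalization expectation.
    """

    seed: int = 0
    out_dir: str = "nucorg_out"
    alpha_locus: float = 0.025
    alpha_expr: float = 0.05
    fold: float = 1.25
    min_run: int = 2
    min_log2: float = 0.8
    top_k: int = 10
    zone_bp: int = 10000
    coloc_p0: float = 0.09
    n_cells: int = 200
    n_genes: int = 6000
    expr_reps: int = 3

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        for name in ("alpha_locus", "alpha_expr", "coloc_p0"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.fold <= 1:
            raise ValueError(f"fold must exceed 1, got {self.fold}")
        if self.min_run < 1 or self.top_k < 0 or self.zone_bp <= 0:
            raise ValueError("min_run >= 1, top_k >= 0 and zone_bp > 0 required")
        if self.n_cells <= 0 or self.n_genes <= 0 or self.expr_reps < 2:
            raise ValueError("n_cells, n_genes positive and expr_reps >= 2 required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
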
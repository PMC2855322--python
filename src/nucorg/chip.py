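"""Locus-level binding calls and statistics for tiling ChIP-chip tracks.

Each array locus (300-bp, or 100-bp on denser regions) carries eleven
25-nt probes; the locus is called bound ("positive") when the one-sided
exact Wilcoxon signed-rank p-value of its probe log2(IP/input) ratios
against zero falls below alpha = 0.025, and depleted ("negative") on the
lower side.  Downstream statistics follow the shape of the study tables:
maximal runs of consecutive positive loci ("clusters", at least two loci),
the top peaks ranked by their highest locus log2 ratio, per-chromosome
coincidence of two factors' positive sets, presence in terminal
subtelomere zones, paired log2 scatter with a Spearman correlation, and a
promoter-context classification against gene annotations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .signed_rank import signed_rank_pvalues

logger = logging.getLogger(__name__)

__all__ = [
    "BindingCall",
    "BindingTrack",
    "Cluster",
    "call_locus",
    "call_track",
    "find_clusters",
    "top_peaks",
    "coincidence",
    "summarize_coincidence",
    "correlate_tracks",
    "subtelomere_presence",
    "classify_context",
    "map_to_resolution",
    "round_half_up",
]

#: Columns of a probe-level signal table.
PROBE_COLUMNS = ["chrom", "locus_start", "locus_end", "locus_id", "probe_index", "log2_ratio"]

#: Columns of a per-locus calls table inside a BindingTrack.
CALL_COLUMNS = [
    "locus_id",
    "chrom",
    "start",
    "end",
    "resolution",
    "log2_ratio",
    "p_up",
    "p_down",
    "status",
]

MIN_PROBES = 5


def round_half_up(x: float) -> int:
    """Integer percentage rounding used throughout the study tables."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class BindingCall:
    locus_id: str
    chrom: str
    start: int
    end: int
    resolution: int
    log2_ratio: float
    p_up: float
    p_down: float
    status: str  # positive | negative | not_significant


def call_locus(values, alpha: float = 0.025) -> tuple[float, float, float, str]:
    """Call one locus from its probe log2 ratios.

    Returns (median log2 ratio, p_up, p_down, status).  The p-values are
    one-sided exact signed-rank tests against zero; status is "positive"
    when p_up < alpha, "negative" when p_down < alpha, otherwise
    "not_significant".  All-zero probe sets make no call.
    """
    v = np.asarray(values, dtype=float)
    if v.size < MIN_PROBES:
        raise ValueError(f"need at least {MIN_PROBES} probe values, got {v.size}")
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    med = float(np.median(v))
    if np.all(v == 0.0):
        return med, 1.0, 1.0, "not_significant"
    p_up, p_down = signed_rank_pvalues(v)
    if p_up < alpha:
        status = "positive"
    elif p_down < alpha:
        status = "negative"
    else:
        status = "not_significant"
    return med, p_up, p_down, status


@dataclass
class BindingTrack:
    """Ordered per-locus binding calls for one factor in one condition."""

    calls: pd.DataFrame
    factor: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in CALL_COLUMNS if c not in self.calls.columns]
        if missing:
            raise ValueError(f"calls table missing columns: {missing}")
        self.calls = (
            self.calls.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        )
        for chrom, sub in self.calls.groupby("chrom", sort=False):
            if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping loci on {chrom}")

    @property
    def positive(self) -> pd.DataFrame:
        return self.calls[self.calls["status"] == "positive"]

    def positive_ids(self) -> set[str]:
        return set(self.positive["locus_id"])

    def __len__(self) -> int:
        return len(self.calls)


def call_track(
    probe_table: pd.DataFrame,
    alpha: float = 0.025,
    factor: str = "",
    condition: str = "",
) -> BindingTrack:
    """Call every locus of a probe-level signal table.

    The table follows the probe schema (chrom, locus_start, locus_end,
    locus_id, probe_index, log2_ratio).  A locus id mapped to more than
    one interval is rejected.
    """
    missing = [c for c in PROBE_COLUMNS if c not in probe_table.columns]
    if missing:
        raise ValueError(f"probe table missing columns: {missing}")
    if probe_table.empty:
        empty = pd.DataFrame(columns=CALL_COLUMNS)
        return BindingTrack(calls=empty, factor=factor, condition=condition)

    spans = probe_table.groupby("locus_id")[["chrom", "locus_start", "locus_end"]].nunique()
    dup = spans[(spans > 1).any(axis=1)]
    if not dup.empty:
        raise ValueError(f"duplicate locus ids with conflicting coordinates: {list(dup.index)[:5]}")

    rows = []
    grouped = probe_table.groupby(["chrom", "locus_start", "locus_end", "locus_id"], sort=True)
    for (chrom, start, end, locus_id), grp in grouped:
        med, p_up, p_down, status = call_locus(grp["log2_ratio"].to_numpy(), alpha=alpha)
        rows.append(
            {
                "locus_id": locus_id,
                "chrom": chrom,
                "start": int(start),
                "end": int(end),
                "resolution": int(end - start),
                "log2_ratio": med,
                "p_up": p_up,
                "p_down": p_down,
                "status": status,
            }
        )
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return BindingTrack(calls=calls, factor=factor, condition=condition)


@dataclass(frozen=True)
class Cluster:
    chrom: str
    start: int
    end: int
    n_loci: int
    peak_log2: float


def find_clusters(track: BindingTrack, min_run: int = 2) -> list[Cluster]:
    """Maximal runs of >= min_run consecutive positive loci.

    Consecutive means adjacent on the tiling grid (the next locus starts
    where the previous one ends, on the same chromosome).
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    clusters: list[Cluster] = []
    for chrom, sub in track.calls.groupby("chrom", sort=True):
        run: list[pd.Series] = []
        prev_end = None
        for _, row in sub.iterrows():
            contiguous = prev_end is not None and row["start"] == prev_end
            if row["status"] == "positive" and (not run or contiguous):
                run.append(row)
            else:
                if len(run) >= min_run:
                    clusters.append(_run_to_cluster(chrom, run))
                run = [row] if row["status"] == "positive" else []
            prev_end = row["end"]
        if len(run) >= min_run:
            clusters.append(_run_to_cluster(chrom, run))
    return clusters


def _run_to_cluster(chrom: str, run: list[pd.Series]) -> Cluster:
    return Cluster(
        chrom=chrom,
        start=int(run[0]["start"]),
        end=int(run[-1]["end"]),
        n_loci=len(run),
        peak_log2=float(max(r["log2_ratio"] for r in run)),
    )


def top_peaks(
    track: BindingTrack, k: int = 10, min_log2: float = 0.8, min_run: int = 2
) -> list[Cluster]:
    """The k highest clusters whose peak locus log2 ratio exceeds min_log2.

    Clusters are ranked by peak_log2 descending (ties broken by position)
    after filtering peak_log2 > min_log2.
    """
    clusters = find_clusters(track, min_run=min_run)
    eligible = [c for c in clusters if c.peak_log2 > min_log2]
    eligible.sort(key=lambda c: (-c.peak_log2, c.chrom, c.start))
    return eligible[:k]


def map_to_resolution(track: BindingTrack, resolution: int = 300) -> BindingTrack:
    """Aggregate finer loci onto a coarser grid by containment.

    A target locus is positive when any contained locus is positive; its
    log2 ratio is the maximum over members.  Loci already at the target
    resolution pass through unchanged.
    """
    calls = track.calls
    if calls.empty or (calls["resolution"] == resolution).all():
        return track
    df = calls.copy()
    df["_bin"] = (df["start"] // resolution) * resolution
    rows = []
    for (chrom, b), grp in df.groupby(["chrom", "_bin"], sort=True):
        rows.append(
            {
                "locus_id": f"{chrom}:{b}-{b + resolution}",
                "chrom": chrom,
                "start": int(b),
                "end": int(b + resolution),
                "resolution": resolution,
                "log2_ratio": float(grp["log2_ratio"].max()),
                "p_up": float(grp["p_up"].min()),
                "p_down": float(grp["p_down"].min()),
                "status": "positive"
                if (grp["status"] == "positive").any()
                else ("negative" if (grp["status"] == "negative").any() else "not_significant"),
            }
        )
    return BindingTrack(
        calls=pd.DataFrame(rows, columns=CALL_COLUMNS),
        factor=track.factor,
        condition=track.condition,
    )


def summarize_coincidence(counts: pd.DataFrame) -> pd.DataFrame:
    """Percentages and pooled total for per-chromosome coincidence counts.

    ``counts`` has one row per chromosome with columns chrom,
    detectable_loci, a_positive, coincident.  Adds a "total" row and the
    two integer percentages (A-positive as % of detectable; coincident as
    % of A-positive), rounded half-up as the study tables print them.
    """
    required = ["chrom", "detectable_loci", "a_positive", "coincident"]
    missing = [c for c in required if c not in counts.columns]
    if missing:
        raise ValueError(f"counts table missing columns: {missing}")
    bad = counts[
        (counts["coincident"] > counts["a_positive"])
        | (counts["a_positive"] > counts["detectable_loci"])
    ]
    if not bad.empty:
        raise ValueError("require coincident <= a_positive <= detectable_loci per row")
    df = counts[required].copy()
    total = pd.DataFrame(
        [
            {
                "chrom": "total",
                "detectable_loci": int(df["detectable_loci"].sum()),
                "a_positive": int(df["a_positive"].sum()),
                "coincident": int(df["coincident"].sum()),
            }
        ]
    )
    df = pd.concat([df, total], ignore_index=True)
    df["a_positive_pct"] = [
        round_half_up(100.0 * a / d) if d else 0
        for a, d in zip(df["a_positive"], df["detectable_loci"])
    ]
    df["coincident_pct"] = [
        round_half_up(100.0 * c / a) if a else 0
        for c, a in zip(df["coincident"], df["a_positive"])
    ]
    return df


def coincidence(
    a: BindingTrack, b: BindingTrack, resolution: int = 300
) -> pd.DataFrame:
    """Per-chromosome coincidence of factor B's positives among factor A's.

    Both tracks are mapped onto the shared coarse grid (100-bp loci fall
    into their containing 300-bp locus) and must then cover identical
    loci.  Returns the coincidence table with counts, integer percentages
    and a pooled "total" row.
    """
    am = map_to_resolution(a, resolution)
    bm = map_to_resolution(b, resolution)
    key = ["chrom", "start", "end"]
    left = am.calls[key + ["status"]].rename(columns={"status": "status_a"})
    right = bm.calls[key + ["status"]].rename(columns={"status": "status_b"})
    merged = left.merge(right, on=key, how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        raise ValueError("tracks do not share a locus grid after resolution mapping")
    rows = []
    for chrom, sub in merged.groupby("chrom", sort=True):
        a_pos = sub["status_a"] == "positive"
        rows.append(
            {
                "chrom": chrom,
                "detectable_loci": int(len(sub)),
                "a_positive": int(a_pos.sum()),
                "coincident": int((a_pos & (sub["status_b"] == "positive")).sum()),
            }
        )
    return summarize_coincidence(pd.DataFrame(rows))


def correlate_tracks(
    a: BindingTrack, b: BindingTrack, subset: str = "a_positive", resolution: int = 300
) -> tuple[pd.DataFrame, float, float]:
    """Paired locus log2 ratios of two tracks with a Spearman correlation.

    ``subset`` restricts the pairs: "a_positive" (default, the scatter of
    the study's supplementary comparison), "b_positive", or "all".
    Returns (paired table, rho, p).
    """
    am = map_to_resolution(a, resolution)
    bm = map_to_resolution(b, resolution)
    key = ["chrom", "start", "end"]
    merged = am.calls[key + ["locus_id", "log2_ratio", "status"]].merge(
        bm.calls[key + ["log2_ratio", "status"]],
        on=key,
        suffixes=("_a", "_b"),
        how="inner",
    )
    if subset == "a_positive":
        merged = merged[merged["status_a"] == "positive"]
    elif subset == "b_positive":
        merged = merged[merged["status_b"] == "positive"]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    if merged.empty:
        raise ValueError(f"no paired loci in subset {subset!r}")
    rho, p = stats.spearmanr(merged["log2_ratio_a"], merged["log2_ratio_b"])
    paired = merged[["locus_id", "chrom", "start", "end", "log2_ratio_a", "log2_ratio_b"]]
    return paired.reset_index(drop=True), float(rho), float(p)


def subtelomere_presence(
    track: BindingTrack, chrom_sizes: pd.DataFrame, zone_bp: int = 10000
) -> pd.DataFrame:
    """Positive loci intersecting the terminal zone_bp of each chromosome arm.

    ``chrom_sizes`` has columns chrom, length.  One row per arm (L/R) per
    chromosome present in the track; a right-arm-only contig (a name
    ending in "R" whose loci start at 0) still reports both ends of the
    covered segment.
    """
    if zone_bp <= 0:
        raise ValueError("zone_bp must be positive")
    sizes = dict(zip(chrom_sizes["chrom"], chrom_sizes["length"]))
    rows = []
    for chrom, sub in track.calls.groupby("chrom", sort=True):
        if chrom not in sizes:
            raise ValueError(f"chromosome {chrom!r} absent from the sizes table")
        length = int(sizes[chrom])
        pos = sub[sub["status"] == "positive"]
        for arm, zs, ze in (
            ("L", 0, min(zone_bp, length)),
            ("R", max(length - zone_bp, 0), length),
        ):
            n = int(((pos["start"] < ze) & (pos["end"] > zs)).sum())
            rows.append(
                {"chrom": chrom, "arm": arm, "zone_start": zs, "zone_end": ze, "n_positive": n}
            )
    return pd.DataFrame(rows)


#: Distance upstream of a start codon that still counts as promoter.
PROMOTER_BP = 400

CONTEXT_LABELS = ("divergent_promoter", "single_promoter", "ORF_internal", "intergenic_other")


def classify_context(track: BindingTrack, genes: pd.DataFrame) -> pd.Series:
    """Label each locus by its position relative to gene annotations.

    ``genes`` uses internal 0-based half-open coordinates with columns
    gene_id, chrom, start, end, strand (the reader converts from GFF3).
    A locus overlapping the shared intergenic gap between two divergently
    transcribed gene starts, within PROMOTER_BP of at least one start, is
    a divergent_promoter; overlapping a single gene's upstream flank
    (<= PROMOTER_BP of its start codon) is single_promoter; wholly inside
    an ORF is ORF_internal; anything else is intergenic_other.
    """
    if genes.empty:
        raise ValueError("no gene annotations supplied")
    if not genes["strand"].isin(["+", "-"]).all():
        bad = genes.loc[~genes["strand"].isin(["+", "-"]), "gene_id"].tolist()
        raise ValueError(f"strandless gene records: {bad[:5]}")

    flanks: dict[str, list[tuple[int, int]]] = {}
    divergent: dict[str, list[tuple[int, int]]] = {}
    orfs: dict[str, list[tuple[int, int]]] = {}
    for chrom, sub in genes.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        orfs[chrom] = list(zip(sub["start"], sub["end"]))
        fl = []
        for _, g in sub.iterrows():
            if g["strand"] == "+":
                fl.append((max(0, g["start"] - PROMOTER_BP), g["start"]))
            else:
                fl.append((g["end"], g["end"] + PROMOTER_BP))
        flanks[chrom] = fl
        div = []
        recs = sub.to_dict("records")
        for left, right in zip(recs, recs[1:]):
            if left["strand"] == "-" and right["strand"] == "+" and left["end"] < right["start"]:
                # gap between the two head-to-head start codons, but only
                # the part within promoter distance of either start
                gap = (left["end"], right["start"])
                windows = [
                    (gap[0], min(gap[1], gap[0] + PROMOTER_BP)),
                    (max(gap[0], gap[1] - PROMOTER_BP), gap[1]),
                ]
                for ws, we in windows:
                    if ws < we:
                        div.append((ws, we))
        divergent[chrom] = div

    def overlaps(s: int, e: int, intervals: list[tuple[int, int]]) -> bool:
        return any(s < ie and e > is_ for is_, ie in intervals)

    labels = []
    for _, row in track.calls.iterrows():
        chrom, s, e = row["chrom"], int(row["start"]), int(row["end"])
        if overlaps(s, e, divergent.get(chrom, [])):
            labels.append("divergent_promoter")
        elif overlaps(s, e, flanks.get(chrom, [])):
            labels.append("single_promoter")
        elif any(s >= is_ and e <= ie for is_, ie in orfs.get(chrom, [])):
            labels.append("ORF_internal")
        else:
            labels.append("intergenic_other")
    return pd.Series(labels, index=track.calls["locus_id"].to_numpy(), name="context")
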
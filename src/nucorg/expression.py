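"""Replicate-level differential expression and set-overlap summaries.

Expression is a genes x samples matrix of log2 intensities with at least
three replicate arrays per strain.  Each gene is tested mutant vs
wild-type with a Welch two-sample t-test on the replicate log2 values;
a gene counts as misregulated when the change is at least 1.25-fold
(|mean difference of log2| >= log2 1.25, boundary inclusive) and the raw
p-value is below 0.05.  No multiple-testing correction is applied — the
analysis deliberately mirrors the raw-p thresholding convention of the
study design it reimplements; see docs/methods.md.  Overlap summaries,
ranked top tables (with the not-significant-in-the-second-mutant entries
flagged for parenthesized display) and per-class effect summaries follow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .chip import round_half_up

__all__ = [
    "ExpressionMatrix",
    "OverlapSummary",
    "test_all",
    "classify_changes",
    "overlap",
    "top_table",
    "format_top_table",
    "class_effect_summary",
]

RESULT_COLUMNS = ["gene", "log2_ratio", "t", "p", "significant", "changed", "direction"]


@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes x samples) plus a sample-to-strain map."""

    values: pd.DataFrame
    strains: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        unmapped = [s for s in self.values.columns if s not in self.strains]
        if unmapped:
            raise ValueError(f"samples without a strain label: {unmapped[:5]}")

    def samples_of(self, strain: str) -> list[str]:
        cols = [s for s in self.values.columns if self.strains[s] == strain]
        if not cols:
            raise ValueError(f"no samples for strain {strain!r}")
        return cols

    @property
    def genes(self) -> pd.Index:
        return self.values.index


def test_all(
    matrix: ExpressionMatrix,
    mutant: str,
    wt: str = "WT",
    fold: float = 1.25,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-gene two-sample t-test of mutant vs wild-type replicates.

    The default is the pooled-variance Student t: with three replicates
    per strain the Welch approximation is markedly conservative (its
    realized type-I error at 3+3 normal replicates is near 3%), whereas
    the pooled test holds the nominal 5% level exactly; pass
    ``equal_var=False`` for Welch when the replicate variances genuinely
    differ.

    Returns one row per gene with the mutant-minus-WT mean log2 ratio,
    the t statistic and raw p, and the threshold flags: ``significant``
    (p < alpha), ``changed`` (|log2 ratio| >= log2(fold), inclusive) and
    ``direction`` in {up, down, none} (none unless both flags hold).

    Degenerate zero-variance genes report p = 1 when the group means are
    equal and p = 0 otherwise.
    """
    if fold <= 1:
        raise ValueError(f"fold threshold must exceed 1, got {fold}")
    mut_cols = matrix.samples_of(mutant)
    wt_cols = matrix.samples_of(wt)
    if len(mut_cols) < 2 or len(wt_cols) < 2:
        raise ValueError("need at least two replicates per strain for a t-test")
    mut = matrix.values[mut_cols].to_numpy(dtype=float)
    ref = matrix.values[wt_cols].to_numpy(dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(mut, ref, axis=1, equal_var=equal_var)
    diff = mut.mean(axis=1) - ref.mean(axis=1)

    degenerate = (mut.var(axis=1) == 0) & (ref.var(axis=1) == 0)
    equal_means = degenerate & np.isclose(diff, 0.0)
    shifted = degenerate & ~np.isclose(diff, 0.0)
    t = np.where(equal_means, 0.0, t)
    p = np.where(equal_means, 1.0, p)
    t = np.where(shifted, np.copysign(np.inf, diff), t)
    p = np.where(shifted, 0.0, p)

    log2_fold = math.log2(fold)
    significant = p < alpha
    changed = np.abs(diff) >= log2_fold
    direction = np.where(
        significant & changed & (diff > 0),
        "up",
        np.where(significant & changed & (diff < 0), "down", "none"),
    )
    return pd.DataFrame(
        {
            "gene": matrix.genes,
            "log2_ratio": diff,
            "t": t,
            "p": p,
            "significant": significant,
            "changed": changed,
            "direction": direction,
        }
    ).reset_index(drop=True)


def classify_changes(
    results: pd.DataFrame, fold: float = 1.25, alpha: float = 0.05
) -> tuple[set[str], set[str]]:
    """Up- and down-regulated gene sets from a results table.

    up = significant and log2_ratio >= log2(fold); down analogously with
    <= -log2(fold).  The fold boundary is inclusive.
    """
    if fold <= 1:
        raise ValueError(f"fold threshold must exceed 1, got {fold}")
    log2_fold = math.log2(fold)
    sig = results["p"] < alpha
    up = set(results.loc[sig & (results["log2_ratio"] >= log2_fold), "gene"])
    down = set(results.loc[sig & (results["log2_ratio"] <= -log2_fold), "gene"])
    return up, down


@dataclass(frozen=True)
class OverlapSummary:
    n_a: int
    n_b: int
    n_both: int
    pct_a_in_b: int
    pct_b_in_a: int

    def as_dict(self) -> dict[str, int]:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_both": self.n_both,
            "pct_a_in_b": self.pct_a_in_b,
            "pct_b_in_a": self.pct_b_in_a,
        }


def overlap(a: set[str], b: set[str]) -> OverlapSummary:
    """Exact set intersection with integer-rounded directional percentages."""
    both = len(a & b)
    return OverlapSummary(
        n_a=len(a),
        n_b=len(b),
        n_both=both,
        pct_a_in_b=round_half_up(100.0 * both / len(a)) if a else 0,
        pct_b_in_a=round_half_up(100.0 * both / len(b)) if b else 0,
    )


def top_table(
    results_1: pd.DataFrame,
    results_2: pd.DataFrame,
    k: int = 40,
    class_labels: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Top k genes by the first mutant's log2 ratio, descending.

    The second mutant's ratio is carried alongside with a flag
    (``ratio_2_not_significant``) marking entries whose second-mutant p
    is >= alpha; the table writer renders those in parentheses.  Both
    result tables must cover the same gene universe.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if set(results_1["gene"]) != set(results_2["gene"]):
        raise ValueError("result tables cover different gene universes")
    merged = results_1.merge(results_2, on="gene", suffixes=("_1", "_2"))
    merged = merged.sort_values(
        ["log2_ratio_1", "gene"], ascending=[False, True], kind="mergesort"
    ).head(k)
    out = pd.DataFrame(
        {
            "gene": merged["gene"],
            "log2_ratio_1": merged["log2_ratio_1"],
            "log2_ratio_2": merged["log2_ratio_2"],
            "ratio_2_not_significant": merged["p_2"] >= alpha,
        }
    )
    labels = class_labels or {}
    out["class"] = [labels.get(g, "") for g in out["gene"]]
    return out.reset_index(drop=True)


def format_top_table(table: pd.DataFrame, digits: int = 2) -> pd.DataFrame:
    """Render a top table with parenthesized non-significant second ratios."""
    shown = []
    for _, row in table.iterrows():
        txt = f"{row['log2_ratio_2']:.{digits}f}"
        shown.append(f"({txt})" if row["ratio_2_not_significant"] else txt)
    out = table.copy()
    out["log2_ratio_2"] = shown
    return out.drop(columns=["ratio_2_not_significant"])


def class_effect_summary(
    results_1: pd.DataFrame,
    results_2: pd.DataFrame,
    class_labels: Mapping[str, str],
    class_label: str,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Paired log2 ratios of genes significant in both mutants, by class.

    Returns the paired scatter rows restricted to genes significant
    (p < alpha) in both mutants, with an ``in_class`` marker, and the
    class means of the two mutants' log2 ratios over that restriction.
    """
    if class_label not in set(class_labels.values()):
        raise ValueError(f"unknown class label {class_label!r}")
    merged = results_1.merge(results_2, on="gene", suffixes=("_1", "_2"))
    sig_both = merged[(merged["p_1"] < alpha) & (merged["p_2"] < alpha)].copy()
    sig_both["in_class"] = [class_labels.get(g) == class_label for g in sig_both["gene"]]
    rows = sig_both[["gene", "log2_ratio_1", "log2_ratio_2", "in_class"]].reset_index(drop=True)
    members = rows[rows["in_class"]]
    summary = {
        "class": class_label,
        "n": int(len(members)),
        "mean_log2_ratio_1": float(members["log2_ratio_1"].mean()) if len(members) else float("nan"),
        "mean_log2_ratio_2": float(members["log2_ratio_2"].mean()) if len(members) else float("nan"),
    }
    return rows, summary
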
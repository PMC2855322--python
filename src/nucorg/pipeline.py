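"""End-to-end demo pipeline: simulate every data type, score every stage.

Stage seeds are spawned deterministically from the single config seed,
all thresholds and seeds are logged, and every output table carries the
config hash, so a config re-run is byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import chip, expression, io, simulate, zones

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(config: io.PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run simulate -> score for all three assays; write tables; return results."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"nucorg config={config.hash()} seed={config.seed}"
    logger.info(
        "pipeline start: %s alpha_locus=%s alpha_expr=%s fold=%s min_run=%s "
        "min_log2=%s zone_bp=%s coloc_p0=%s",
        tag, config.alpha_locus, config.alpha_expr, config.fold,
        config.min_run, config.min_log2, config.zone_bp, config.coloc_p0,
    )
    seed_spots, seed_anchored, seed_chip, seed_expr = _stage_seeds(config.seed)
    results: dict = {"config_hash": config.hash()}

    try:
        # --- zone assay: a random control and an anchored population -----
        control = simulate.simulate_spots(
            simulate.SpotSimConfig(n_cells=config.n_cells, seed=seed_spots,
                                   coloc_prob=config.coloc_p0)
        )
        control["condition"] = "control"
        anchored = simulate.simulate_spots(
            simulate.SpotSimConfig(
                n_cells=config.n_cells, zone_probs=(0.49, 0.30, 0.21),
                coloc_prob=0.224, seed=seed_anchored,
            )
        )
        anchored["condition"] = "anchored"
        spots = pd.concat([control, anchored], ignore_index=True)
        io.write_table(spots, out / "spots.tsv", comment=tag)
        report = zones.zone_report(spots, group_by=["condition", "stage"])
        io.write_table(report, out / "zone_table.tsv", comment=tag)
        coloc = {}
        for cond, sub in spots.groupby("condition"):
            res = zones.test_colocalization(
                int(sub["coloc"].sum()), len(sub), p0=config.coloc_p0
            )
            coloc[cond] = {"k": res.k, "n": res.n, "percentage": res.percentage, "p": res.p}
        (out / "colocalization.json").write_text(json.dumps(coloc, indent=2))
        results["zone_report"] = report
        results["colocalization"] = coloc

        # --- tiling ChIP ---------------------------------------------------
        sim = simulate.simulate_tiling(simulate.TilingSimConfig(seed=seed_chip))
        track_a = chip.call_track(sim.probes["A"], alpha=config.alpha_locus, factor="A")
        track_b = chip.call_track(sim.probes["B"], alpha=config.alpha_locus, factor="B")
        io.write_bed(io.calls_to_bed(track_a), out / "calls_A.bed", header=tag)
        io.write_bed(io.calls_to_bed(track_b), out / "calls_B.bed", header=tag)
        peaks = chip.top_peaks(
            track_a, k=config.top_k, min_log2=config.min_log2, min_run=config.min_run
        )
        io.write_bed(io.clusters_to_bed(peaks), out / "clusters_A.bed", header=tag)
        coin = chip.coincidence(track_a, track_b)
        io.write_table(coin, out / "coincidence.tsv", comment=tag)
        sizes = pd.DataFrame(
            [{"chrom": c, "length": l} for c, l in simulate.DEFAULT_CHROM_SIZES]
        )
        subtel = chip.subtelomere_presence(track_a, sizes, zone_bp=config.zone_bp)
        io.write_table(subtel, out / "subtelomere.tsv", comment=tag)
        paired, rho, rho_p = chip.correlate_tracks(track_a, track_b)
        io.write_table(paired, out / "scatter.tsv", comment=tag)
        results.update(
            {
                "track_a": track_a,
                "track_b": track_b,
                "coincidence": coin,
                "subtelomere": subtel,
                "spearman": {"rho": rho, "p": rho_p},
                "chip_truth": sim.truth,
            }
        )

        # --- expression ----------------------------------------------------
        cfg = simulate.default_expr_config(
            seed=seed_expr, n_genes=config.n_genes, n_reps=config.expr_reps
        )
        matrix, truth = simulate.simulate_expression(cfg)
        res_a = expression.test_all(matrix, "mutantA", "WT",
                                    fold=config.fold, alpha=config.alpha_expr)
        res_b = expression.test_all(matrix, "mutantB", "WT",
                                    fold=config.fold, alpha=config.alpha_expr)
        io.write_table(res_a, out / "de_mutantA.tsv", comment=tag)
        io.write_table(res_b, out / "de_mutantB.tsv", comment=tag)
        up_a, down_a = expression.classify_changes(res_a, config.fold, config.alpha_expr)
        up_b, down_b = expression.classify_changes(res_b, config.fold, config.alpha_expr)
        overlaps = {
            "down": expression.overlap(down_b, down_a).as_dict(),
            "up": expression.overlap(up_b, up_a).as_dict(),
        }
        (out / "overlap.json").write_text(json.dumps(overlaps, indent=2))
        top = expression.top_table(res_a, res_b, k=40, class_labels=cfg.class_labels,
                                   alpha=config.alpha_expr)
        io.write_table(expression.format_top_table(top), out / "top_table.tsv", comment=tag)
        _, rp_summary = expression.class_effect_summary(
            res_a, res_b, cfg.class_labels, "RP", alpha=config.alpha_expr
        )
        (out / "rp_class.json").write_text(json.dumps(rp_summary, indent=2))
        results.update(
            {
                "de_mutantA": res_a,
                "de_mutantB": res_b,
                "overlaps": overlaps,
                "top_table": top,
                "rp_class": rp_summary,
                "expr_truth": truth,
            }
        )
    except Exception as err:  # annotate which stage died
        raise RuntimeError(f"pipeline stage failed: {err}") from err

    meta = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "stage_seeds": [seed_spots, seed_anchored, seed_chip, seed_expr],
        "thresholds": {
            "alpha_locus": config.alpha_locus,
            "alpha_expr": config.alpha_expr,
            "fold": config.fold,
            "min_run": config.min_run,
            "min_log2": config.min_log2,
            "zone_bp": config.zone_bp,
            "coloc_p0": config.coloc_p0,
        },
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    logger.info("pipeline done: outputs in %s", out)
    return results
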
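"""Seeded generators for spot positions, tiling ChIP signals, expression.

Every stage of the pipeline can be exercised without external downloads:

* ``simulate_spots`` draws spot-to-envelope distances in the focal-plane
  disc.  With zone probabilities (1/3, 1/3, 1/3) the radial positions
  are exactly area-uniform (r = R*sqrt(u)); otherwise a zone is drawn
  first and the position is area-uniform within that annulus.  Cell-cycle
  stage (G1/S) and a per-cell Bernoulli pore-colocalization event ride
  along.
* ``simulate_tiling`` plants a binding landscape for a factor A and a
  jointly drawn factor B on a 300-bp (or 100-bp) locus grid, eleven
  probes per locus, Gaussian probe noise, with the conditional overlap
  P(B | A) as an explicit dial and the planted positive sets recorded as
  ground truth.  The default grid holds 8,441 detectable loci across
  four chromosomes, mirroring the scale of a four-chromosome tiling
  design (1322 + 4857 + 1849 + 413 loci).
* ``simulate_expression`` produces replicate log2 intensity matrices for
  a wild-type and two mutant strains with planted up/down gene sets
  (including a ribosomal-protein-like class) and replicate noise.

Identical config and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .zones import derive_zone_boundaries

__all__ = [
    "SpotSimConfig",
    "TilingSimConfig",
    "ExprSimConfig",
    "TilingSim",
    "simulate_spots",
    "simulate_tiling",
    "simulate_expression",
    "design_planted_sets",
    "default_expr_config",
    "DEFAULT_CHROM_SIZES",
]

#: Four-chromosome grid whose 300-bp locus counts mirror a four-chromosome
#: tiling design: 1322 + 4857 + 1849 + 413 = 8441 detectable loci.
DEFAULT_CHROM_SIZES: tuple[tuple[str, int], ...] = (
    ("chr3", 1322 * 300),
    ("chr4", 4857 * 300),
    ("chr5", 1849 * 300),
    ("chr6R", 413 * 300),
)


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class SpotSimConfig:
    """Spot-position population.

    zone_probs are the target occupancies of zones 1 (peripheral), 2, 3;
    they must sum to one.  The nuclear diameter is fixed (2.0 um by
    default) — only the distance-to-diameter ratio matters downstream.
    """

    n_cells: int = 200
    zone_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    g1_fraction: float = 0.5
    coloc_prob: float = 0.09
    diameter_um: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError(f"n_cells must be positive, got {self.n_cells}")
        if len(self.zone_probs) != 3:
            raise ValueError("zone_probs must have three entries")
        for i, p in enumerate(self.zone_probs, 1):
            _check_prob(f"zone_probs[{i}]", p)
        if abs(sum(self.zone_probs) - 1.0) > 1e-12:
            raise ValueError(f"zone_probs must sum to 1, got {sum(self.zone_probs)}")
        _check_prob("g1_fraction", self.g1_fraction)
        _check_prob("coloc_prob", self.coloc_prob)
        if self.diameter_um <= 0:
            raise ValueError("diameter_um must be positive")


def simulate_spots(config: SpotSimConfig) -> pd.DataFrame:
    """Simulate one imaged-cell table (cell_id, stage, distances, coloc).

    Per cell a zone is drawn from zone_probs and the radial position is
    area-uniform within that zone's annulus of the unit-diameter disc;
    the uniform mixture therefore reproduces the area-uniform null
    exactly.  Distances are reported in micrometres.
    """
    rng = np.random.default_rng(config.seed)
    b = derive_zone_boundaries()
    n = config.n_cells
    zone = rng.choice(3, size=n, p=np.asarray(config.zone_probs, dtype=float))

    # annulus radii (diameter units, measured from the centre)
    rho_out = np.choose(zone, [0.5, 0.5 - b.b1, 0.5 - b.b2])
    rho_in = np.choose(zone, [0.5 - b.b1, 0.5 - b.b2, 0.0])
    u = rng.random(n)
    # u=0 maps to the outer edge so each zone's ratio interval stays
    # half-open on the inner side ([0, b1), [b1, b2), [b2, 0.5)).
    rho = np.sqrt(rho_out**2 - u * (rho_out**2 - rho_in**2))
    ratio = 0.5 - rho

    stage = np.where(rng.random(n) < config.g1_fraction, "G1", "S")
    coloc = rng.random(n) < config.coloc_prob
    return pd.DataFrame(
        {
            "cell_id": [f"cell{i:06d}" for i in range(n)],
            "stage": stage,
            "distance_um": ratio * config.diameter_um,
            "diameter_um": config.diameter_um,
            "coloc": coloc,
        }
    )


@dataclass(frozen=True)
class TilingSimConfig:
    """Planted two-factor binding landscape on a tiling-array grid.

    Bound loci carry per-probe log2 ratios ~ Normal(effect_log2,
    noise_sd); unbound loci ~ Normal(0, noise_sd).  Factor B is drawn
    jointly with A: P(B | A) = cond_overlap_B_given_A, and the rate on
    non-A loci is solved so the marginal of B matches marginal_B.
    """

    chrom_sizes: tuple[tuple[str, int], ...] = DEFAULT_CHROM_SIZES
    locus_size: int = 300
    probes_per_locus: int = 11
    probe_length: int = 25  # metadata only
    bound_fraction_A: float = 0.24
    cond_overlap_B_given_A: float = 0.76
    marginal_B: float = 0.30
    effect_log2: float = 1.5
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.locus_size not in (300, 100):
            raise ValueError(f"locus_size must be 300 or 100, got {self.locus_size}")
        if not self.chrom_sizes:
            raise ValueError("chrom_sizes must not be empty")
        for name, length in self.chrom_sizes:
            if length < self.locus_size:
                raise ValueError(f"chromosome {name!r} shorter than one locus")
        if self.probes_per_locus < 5:
            raise ValueError("need at least five probes per locus")
        _check_prob("bound_fraction_A", self.bound_fraction_A)
        _check_prob("cond_overlap_B_given_A", self.cond_overlap_B_given_A)
        _check_prob("marginal_B", self.marginal_B)
        if self.effect_log2 <= 0:
            raise ValueError("effect_log2 must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.bound_fraction_A < 1.0:
            q = self.rate_B_given_not_A
            if not (0.0 <= q <= 1.0):
                raise ValueError(
                    "marginal_B is infeasible given bound_fraction_A and "
                    f"cond_overlap_B_given_A (implied off-A rate {q:.3f})"
                )

    @property
    def rate_B_given_not_A(self) -> float:
        joint = self.bound_fraction_A * self.cond_overlap_B_given_A
        if self.bound_fraction_A >= 1.0:
            return 0.0
        return (self.marginal_B - joint) / (1.0 - self.bound_fraction_A)


@dataclass
class TilingSim:
    """Probe tables per factor plus the planted ground truth."""

    probes: dict[str, pd.DataFrame]
    truth: dict[str, set[str]]
    loci: pd.DataFrame  # chrom, start, end, locus_id


def _locus_grid(config: TilingSimConfig) -> pd.DataFrame:
    rows = []
    for chrom, length in config.chrom_sizes:
        n_loci = length // config.locus_size
        starts = np.arange(n_loci) * config.locus_size
        for s in starts:
            e = s + config.locus_size
            rows.append((chrom, int(s), int(e), f"{chrom}:{s}-{e}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "locus_id"])


def simulate_tiling(config: TilingSimConfig) -> TilingSim:
    """Simulate probe-level signal tables for factors A and B."""
    rng = np.random.default_rng(config.seed)
    loci = _locus_grid(config)
    n = len(loci)

    bound_a = rng.random(n) < config.bound_fraction_A
    u = rng.random(n)
    bound_b = np.where(
        bound_a, u < config.cond_overlap_B_given_A, u < config.rate_B_given_not_A
    )

    k = config.probes_per_locus
    probes = {}
    for factor, bound in (("A", bound_a), ("B", bound_b)):
        mean = np.where(bound, config.effect_log2, 0.0)
        signal = rng.normal(mean[:, None], config.noise_sd, size=(n, k))
        probes[factor] = pd.DataFrame(
            {
                "chrom": np.repeat(loci["chrom"].to_numpy(), k),
                "locus_start": np.repeat(loci["start"].to_numpy(), k),
                "locus_end": np.repeat(loci["end"].to_numpy(), k),
                "locus_id": np.repeat(loci["locus_id"].to_numpy(), k),
                "probe_index": np.tile(np.arange(k), n),
                "log2_ratio": signal.ravel(),
            }
        )
    truth = {
        "A": set(loci.loc[bound_a, "locus_id"]),
        "B": set(loci.loc[bound_b, "locus_id"]),
    }
    return TilingSim(probes=probes, truth=truth, loci=loci)


@dataclass(frozen=True)
class ExprSimConfig:
    """Replicate expression design with planted up/down sets per mutant.

    planted_up / planted_down map each non-reference strain to a
    gene -> log2-effect dictionary (effects are magnitudes; down effects
    are subtracted).  Per-gene baselines are Normal(baseline_mean,
    baseline_sd); replicate noise is Normal(0, noise_sd) on the log2
    scale.
    """

    n_genes: int = 6000
    n_reps: int = 3
    strains: tuple[str, ...] = ("WT", "mutantA", "mutantB")
    planted_up: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    planted_down: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    class_labels: Mapping[str, str] = field(default_factory=dict)
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_reps < 2:
            raise ValueError("need at least two replicates per strain (t-test undefined)")
        if len(self.strains) < 2:
            raise ValueError("need a reference strain and at least one mutant")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        genes = set(self.gene_ids())
        for strain in set(self.planted_up) | set(self.planted_down):
            if strain not in self.strains:
                raise ValueError(f"planted effects for unknown strain {strain!r}")
            up = set(self.planted_up.get(strain, {}))
            down = set(self.planted_down.get(strain, {}))
            clash = up & down
            if clash:
                raise ValueError(f"genes planted both up and down in {strain!r}: {sorted(clash)[:5]}")
            unknown = (up | down) - genes
            if unknown:
                raise ValueError(f"planted effects for unknown genes: {sorted(unknown)[:5]}")

    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]


def simulate_expression(config: ExprSimConfig):
    """Simulate the expression matrix; returns (ExpressionMatrix, truth).

    ``truth`` maps each mutant to its planted up/down effect dictionaries
    (the ground truth the recovery tests compare against).
    """
    from .expression import ExpressionMatrix  # local to avoid cycle at import

    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids()
    idx = {g: i for i, g in enumerate(genes)}
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)

    columns: dict[str, np.ndarray] = {}
    strains_map: dict[str, str] = {}
    for strain in config.strains:
        effect = np.zeros(config.n_genes)
        for g, e in config.planted_up.get(strain, {}).items():
            effect[idx[g]] += e
        for g, e in config.planted_down.get(strain, {}).items():
            effect[idx[g]] -= e
        for r in range(config.n_reps):
            name = f"{strain}_{r + 1}"
            columns[name] = baseline + effect + rng.normal(0.0, config.noise_sd, config.n_genes)
            strains_map[name] = strain
    values = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    truth = {
        strain: {
            "up": dict(config.planted_up.get(strain, {})),
            "down": dict(config.planted_down.get(strain, {})),
        }
        for strain in config.strains
        if strain in config.planted_up or strain in config.planted_down
    }
    return ExpressionMatrix(values=values, strains=strains_map), truth


def design_planted_sets(
    n_genes: int,
    sizes_b: tuple[int, int] = (375, 506),
    sizes_a: tuple[int, int] = (400, 500),
    inter_mutant_overlap: tuple[float, float] = (0.15, 0.17),
    effect_range: tuple[float, float] = (0.4, 2.3),
    n_rp: int = 60,
    rp_effect_range: tuple[float, float] = (1.4, 2.3),
    rp_effect_range_b: tuple[float, float] = (0.0, 0.8),
    seed: int = 0,
) -> tuple[dict, dict, dict]:
    """Design planted effect dictionaries for two mutants plus an RP class.

    ``sizes_b`` / ``sizes_a`` are (n_up, n_down) for mutants B and A;
    ``inter_mutant_overlap`` is the (up, down) fraction of mutant B's set
    that is also planted in mutant A, realized exactly by construction.
    A ribosomal-protein-like class of ``n_rp`` genes is planted strongly
    up in mutant A and weakly (often sub-threshold) up in mutant B,
    mirroring the coordinately regulated class the analysis summarizes.
    Returns (planted_up, planted_down, class_labels).
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    needed = sum(sizes_a) + sum(sizes_b) + n_rp  # upper bound, overlaps reduce it
    if needed > n_genes // 2:
        # shrink the design proportionally for small gene universes so the
        # planted sets stay a minority of the transcriptome
        scale = (n_genes // 2) / needed
        sizes_a = (max(1, int(sizes_a[0] * scale)), max(1, int(sizes_a[1] * scale)))
        sizes_b = (max(1, int(sizes_b[0] * scale)), max(1, int(sizes_b[1] * scale)))
        n_rp = max(1, int(n_rp * scale))
    pool = list(rng.permutation(genes))

    def take(k: int) -> list[str]:
        out, rest = pool[:k], pool[k:]
        pool[:] = rest
        return out

    def effects(members: Sequence[str], lo: float, hi: float) -> dict[str, float]:
        return {g: float(e) for g, e in zip(members, rng.uniform(lo, hi, len(members)))}

    lo, hi = effect_range
    up_b = take(sizes_b[0])
    down_b = take(sizes_b[1])
    n_up_shared = int(round(inter_mutant_overlap[0] * sizes_b[0]))
    n_down_shared = int(round(inter_mutant_overlap[1] * sizes_b[1]))
    up_a = up_b[:n_up_shared] + take(sizes_a[0] - n_up_shared)
    down_a = down_b[:n_down_shared] + take(sizes_a[1] - n_down_shared)
    rp = take(n_rp)

    planted_up = {
        "mutantA": {**effects(up_a, lo, hi), **effects(rp, *rp_effect_range)},
        "mutantB": {**effects(up_b, lo, hi), **effects(rp, *rp_effect_range_b)},
    }
    planted_down = {
        "mutantA": effects(down_a, lo, hi),
        "mutantB": effects(down_b, lo, hi),
    }
    class_labels = {g: "RP" for g in rp}
    return planted_up, planted_down, class_labels


def default_expr_config(seed: int = 0, n_genes: int = 6000, **kwargs) -> ExprSimConfig:
    """The default study-shaped expression design under one seed."""
    planted_up, planted_down, class_labels = design_planted_sets(n_genes, seed=seed)
    return ExprSimConfig(
        n_genes=n_genes,
        planted_up=planted_up,
        planted_down=planted_down,
        class_labels=class_labels,
        seed=seed,
        **kwargs,
    )
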
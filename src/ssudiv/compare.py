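"""Comparison statistics and pipeline orchestration.

Two distance configurations (e.g. a sub-region versus full length, or a
degraded versus a faithful alignment) are compared by regressing the second
set of pairwise distances on the first through the origin: slope = sum(xy) /
sum(x^2). A slope above 1 means the comparison configuration sees more
genetic diversity than the reference; below 1, less. Pairs whose reference
distance is 0.10 or larger are excluded, because saturation breaks linearity
beyond that range, and fit quality is the squared Pearson product-moment
correlation of the retained pairs. Replicated beta-diversity metrics are
compared with a balanced two-way fixed-effects ANOVA (region x method) and
Tukey honest-significant-difference pairwise tests at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from ssudiv import synthdata
from ssudiv.beta_metrics import SharedTable
from ssudiv.distances import DistanceMatrix, GapPolicy, distance_matrix
from ssudiv.mocksim import MockDesign, run_replicates
from ssudiv.otu_cluster import cluster, partition_at, richness_curve, write_richness_tsv
from ssudiv.phylo_tree import neighbor_joining, phylogenetic_diversity, write_newick
from ssudiv.seqio_regions import apply_mask, extract_region, write_fasta


@dataclass(frozen=True)
class RegressionFit:
    slope_through_origin: float
    pearson_r2: float
    n_pairs_used: int
    reference_filter: float


def regress_origin(x: Sequence[float], y: Sequence[float], x_max: float = 0.10) -> RegressionFit:
    """Through-origin regression of y on x, restricted to x < x_max.

    slope = sum(xy)/sum(x^2); r^2 is the squared Pearson correlation of the
    retained pairs (not the through-origin coefficient of determination).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length and ordering")
    keep = x < x_max
    x, y = x[keep], y[keep]
    if len(x) < 2:
        raise ValueError("fewer than 2 pairs retained by the reference filter")
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("all retained reference distances are zero")
    slope = float(x @ y) / sxx
    if np.std(x) == 0 or np.std(y) == 0:
        r2 = 1.0 if np.allclose(y, slope * x) else 0.0
    else:
        r2 = float(np.corrcoef(x, y)[0, 1]) ** 2
    return RegressionFit(slope, r2, len(x), x_max)


def matched_pairs(dm_x: DistanceMatrix, dm_y: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Distances matched by unordered sequence-id pair across two matrices.

    Pairs present in only one matrix are dropped; both matrices must share at
    least one pair.
    """
    lookup = {frozenset((a, b)): d for a, b, d in dm_y.pairs()}
    xs, ys = [], []
    for a, b, d in dm_x.pairs():
        key = frozenset((a, b))
        if key in lookup:
            xs.append(d)
            ys.append(lookup[key])
    if not xs:
        raise ValueError("no sequence-id pairs shared between the two matrices")
    return np.asarray(xs), np.asarray(ys)


@dataclass(frozen=True)
class GroupComparison:
    anova: pd.DataFrame  # statsmodels anova_lm table
    tukey: pd.DataFrame  # pairwise comparisons with reject flags at alpha=0.05
    nonsignificant_pairs: tuple[tuple[str, str], ...]


def compare_groups(table: pd.DataFrame, factors: tuple[str, str] = ("region", "method"),
                   value: str = "value") -> GroupComparison:
    """Balanced two-way fixed-effects ANOVA plus Tukey HSD on factor-level cells.

    ``table`` holds one row per replicate with the two factor columns and the
    metric value; every factor cell must carry the same replicate count.
    """
    fa, fb = factors
    counts = table.groupby([fa, fb], observed=True)[value].count()
    if counts.nunique() != 1:
        raise ValueError("unbalanced cells: every factor combination needs the same replicate count")
    if table[fa].nunique() < 2 or table[fb].nunique() < 2:
        raise ValueError("each factor needs at least 2 levels")
    model = ols(f"{value} ~ C({fa}) + C({fb}) + C({fa}):C({fb})", data=table).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    cell = table[fa].astype(str) + ":" + table[fb].astype(str)
    tk = pairwise_tukeyhsd(table[value].to_numpy(), cell.to_numpy(), alpha=0.05)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    nonsig = tuple(
        (str(row["group1"]), str(row["group2"]))
        for _, row in tukey.iterrows()
        if not row["reject"]
    )
    return GroupComparison(anova, tukey, nonsig)


@dataclass(frozen=True)
class PipelineConfig:
    """Desk-scale end-to-end run over a synthetic world."""

    world: synthdata.SyntheticWorldConfig = synthdata.SyntheticWorldConfig()
    calculators: tuple[str, ...] = ("one_gap",)
    regions: tuple[tuple[str, int, int], ...] = ()  # (name, ref_start, ref_end)
    perturbations: tuple[str, ...] = ("faithful",)
    apply_lane_style_mask: bool = False
    otu_cutoffs: tuple[float, ...] = (0.03, 0.05, 0.10)
    mock: MockDesign | None = None
    out_dir: str = "pipeline_out"


def run_pipeline(config: PipelineConfig) -> dict:
    """Generate a world and push it through every configured stage.

    Writes alignments, distance summaries, richness curves, trees, regression
    and (when a mock design is given) replicate beta-metric tables under
    ``config.out_dir``; returns the result bundle in memory as well.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config}

    world = synthdata.generate_world(config.world)
    write_fasta(world.truth_alignment, out / "truth.fasta")
    write_newick(world.true_tree, out / "true_tree.nwk")

    from ssudiv.seqio_regions import RegionDef, write_coordinate_map, write_mask

    write_coordinate_map(world.coordinate_map, out / "coordinate_map.tsv")

    alignments = {}
    for mode in config.perturbations:
        alignments[mode] = synthdata.perturb_alignment(world, mode, seed=config.world.seed + 1)
        if mode != "faithful":
            write_fasta(alignments[mode], out / f"aln_{mode}.fasta")

    variants = {}
    for mode, aln in alignments.items():
        variants[(mode, "full", "unmasked")] = aln
        for name, lo, hi in config.regions:
            variants[(mode, name, "unmasked")] = extract_region(aln, world.coordinate_map, RegionDef(name, lo, hi))
        if config.apply_lane_style_mask:
            mask = synthdata.generate_mask(world)
            write_mask(mask, out / "mask.txt")
            variants[(mode, "full", "masked")] = apply_mask(aln, mask)

    matrices = {}
    for key, aln in variants.items():
        for calc in config.calculators:
            matrices[key + (calc,)] = distance_matrix(aln, calc)

    ref_key = ("faithful", "full", "unmasked", config.calculators[0])
    regressions = []
    for key, dm in matrices.items():
        if key == ref_key:
            continue
        xs, ys = matched_pairs(matrices[ref_key], dm)
        try:
            fit = regress_origin(xs, ys)
        except ValueError:
            continue
        regressions.append({"variant": "|".join(key), "slope": fit.slope_through_origin,
                            "r2": fit.pearson_r2, "n": fit.n_pairs_used})
    reg_df = pd.DataFrame(regressions)
    reg_df.to_csv(out / "regressions.tsv", sep="\t", index=False)
    bundle["regressions"] = reg_df

    dm0 = matrices[ref_key]
    sched = cluster(dm0, "furthest")
    write_richness_tsv(richness_curve(sched), out / "richness_full.tsv")
    tree = neighbor_joining(dm0)
    write_newick(tree, out / "nj_tree.nwk")
    bundle["pd"] = phylogenetic_diversity(tree)
    bundle["richness"] = richness_curve(sched)

    if config.mock is not None:
        base = partition_at(sched, config.mock.otu_cutoff)
        metrics_df = run_replicates(base, config.mock, ("jaccard", "morisita_horn"),
                                    tree=tree, sched=sched, cutoffs=config.otu_cutoffs)
        metrics_df.to_csv(out / "mock_metrics.tsv", sep="\t", index=False)
        bundle["mock_metrics"] = metrics_df

    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"seed\t{config.world.seed}\n")
        fh.write(f"n_taxa\t{config.world.n_taxa}\n")
        fh.write(f"variants\t{len(matrices)}\n")
    return bundle
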
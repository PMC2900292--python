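"""Through-origin regression, two-way ANOVA/Tukey, and pipeline direction-of-effect."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ssudiv.compare import (
    PipelineConfig,
    compare_groups,
    matched_pairs,
    regress_origin,
    run_pipeline,
)
from ssudiv.distances import distance_matrix
from ssudiv.seqio_regions import apply_mask
from ssudiv.synthdata import SyntheticWorldConfig, generate_mask, generate_world, perturb_alignment


def test_regress_origin_exact_lines():
    x = np.linspace(0.01, 0.09, 10)
    fit = regress_origin(x, x)
    assert fit.slope_through_origin == pytest.approx(1.0)
    assert fit.pearson_r2 == pytest.approx(1.0)
    fit2 = regress_origin(x, 2 * x)
    assert fit2.slope_through_origin == pytest.approx(2.0)
    assert fit2.pearson_r2 == pytest.approx(1.0)


def test_regress_origin_reference_filter_and_arithmetic_oracle():
    x = np.array([0.02, 0.05, 0.08, 0.12])
    y = np.array([0.03, 0.06, 0.10, 0.20])
    fit = regress_origin(x, y, x_max=0.10)
    assert fit.n_pairs_used == 3
    xr, yr = x[:3], y[:3]
    assert fit.slope_through_origin == pytest.approx(float(xr @ yr) / float(xr @ xr))
    assert fit.pearson_r2 == pytest.approx(float(np.corrcoef(xr, yr)[0, 1]) ** 2)


def test_regress_origin_scale_equivariance():
    rng = np.random.default_rng(2)
    x = rng.uniform(0.01, 0.09, 50)
    y = 1.3 * x + rng.normal(0, 0.005, 50)
    base = regress_origin(x, y)
    scaled = regress_origin(x, 3.0 * y)
    assert scaled.slope_through_origin == pytest.approx(3.0 * base.slope_through_origin)
    assert scaled.pearson_r2 == pytest.approx(base.pearson_r2)


def test_regress_origin_degenerate_inputs():
    with pytest.raises(ValueError):
        regress_origin([0.2, 0.3], [0.2, 0.3], x_max=0.10)  # nothing retained
    with pytest.raises(ValueError):
        regress_origin([0.0, 0.0, 0.0], [0.1, 0.2, 0.3])


def _balanced_table(rng, shift=None):
    rows = []
    for region in ("R1", "R2", "R3"):
        for method in ("m1", "m2"):
            mu = 0.5
            if shift and (region, method) == shift[0]:
                mu += shift[1]
            for _ in range(20):
                rows.append((region, method, rng.normal(mu, 0.02)))
    return pd.DataFrame(rows, columns=["region", "method", "value"])


def test_null_data_mostly_nonsignificant():
    hits = 0
    for seed in range(10):
        gc = compare_groups(_balanced_table(np.random.default_rng(seed)))
        n_pairs = len(gc.tukey)
        if len(gc.nonsignificant_pairs) == n_pairs:
            hits += 1
    assert hits >= 9


def test_extreme_shift_detected_against_all_others():
    gc = compare_groups(_balanced_table(np.random.default_rng(0), shift=(("R2", "m2"), 0.2)))
    shifted = "R2:m2"
    for _, row in gc.tukey.iterrows():
        involves = shifted in (str(row["group1"]), str(row["group2"]))
        if involves:
            assert bool(row["reject"])


def test_anova_matches_hand_sums_of_squares():
    """Balanced 2x2 layout with 3 replicates against a direct SS decomposition."""
    data = {
        ("a", "x"): [3.0, 4.0, 5.0],
        ("a", "y"): [6.0, 7.0, 8.0],
        ("b", "x"): [2.0, 3.0, 4.0],
        ("b", "y"): [9.0, 10.0, 11.0],
    }
    rows = [(fa, fb, v) for (fa, fb), vs in data.items() for v in vs]
    table = pd.DataFrame(rows, columns=["region", "method", "value"])
    gc = compare_groups(table)
    vals = np.array([v for _, _, v in rows])
    grand = vals.mean()
    cell_means = {k: np.mean(v) for k, v in data.items()}
    a_means = {a: np.mean([v for (fa, _), vs in data.items() for v in vs if fa == a]) for a in "ab"}
    b_means = {b: np.mean([v for (_, fb), vs in data.items() for v in vs if fb == b]) for b in "xy"}
    n_rep, n_a, n_b = 3, 2, 2
    ss_a = n_rep * n_b * sum((m - grand) ** 2 for m in a_means.values())
    ss_b = n_rep * n_a * sum((m - grand) ** 2 for m in b_means.values())
    ss_ab = n_rep * sum(
        (cell_means[(a, b)] - a_means[a] - b_means[b] + grand) ** 2 for a in "ab" for b in "xy"
    )
    ss_err = sum((v - cell_means[k]) ** 2 for k, vs in data.items() for v in vs)
    anova = gc.anova
    assert anova.loc["C(region)", "sum_sq"] == pytest.approx(ss_a)
    assert anova.loc["C(method)", "sum_sq"] == pytest.approx(ss_b)
    assert anova.loc["C(region):C(method)", "sum_sq"] == pytest.approx(ss_ab)
    assert anova.loc["Residual", "sum_sq"] == pytest.approx(ss_err)


def test_unbalanced_cells_rejected():
    table = pd.DataFrame(
        [("R1", "m1", 0.5)] * 5 + [("R1", "m2", 0.5)] * 4 + [("R2", "m1", 0.5)] * 5 + [("R2", "m2", 0.5)] * 5,
        columns=["region", "method", "value"],
    )
    with pytest.raises(ValueError, match="unbalanced"):
        compare_groups(table)


SMALL_LAYOUT = (("conserved", 60), ("variable", 30), ("conserved", 60))


def _mean_slope(variant_fn, n_seeds=20):
    slopes = []
    for seed in range(n_seeds):
        world = generate_world(SyntheticWorldConfig(n_taxa=10, region_layout=SMALL_LAYOUT, seed=seed))
        base = distance_matrix(world.truth_alignment, "one_gap")
        other = variant_fn(world, seed)
        xs, ys = matched_pairs(base, other)
        try:
            slopes.append(regress_origin(xs, ys).slope_through_origin)
        except ValueError:
            continue
    return float(np.mean(slopes))


def test_degraded_alignment_inflates_slope_above_one():
    """Poorly aligned variable regions predict extra genetic diversity (slope > 1)."""
    slope = _mean_slope(
        lambda w, s: distance_matrix(perturb_alignment(w, "shuffle_variable", seed=s + 500), "one_gap")
    )
    assert slope > 1.0


def test_mask_filtering_removes_diversity_slope_below_one():
    """Dropping variable columns discards divergence, pulling the slope under 1."""
    slope = _mean_slope(
        lambda w, s: distance_matrix(apply_mask(w.truth_alignment, generate_mask(w)), "one_gap")
    )
    assert slope < 1.0


def test_gap_policy_slopes_bracket_one():
    """each_gap reads at least as much diversity as one_gap; ignore_gap at most (20 seeds)."""
    each = _mean_slope(lambda w, s: distance_matrix(w.truth_alignment, "each_gap"))
    ignore = _mean_slope(lambda w, s: distance_matrix(w.truth_alignment, "ignore_gap"))
    assert each >= 1.0 >= ignore


def test_region_slope_monotone_in_rate_multiplier():
    """A faster-evolving region regresses against full length with a larger slope."""
    from ssudiv.seqio_regions import RegionDef, extract_region

    mean_slopes = []
    for mult in (1.0, 3.0, 6.0):
        slopes = []
        for seed in range(20):
            cfg = SyntheticWorldConfig(n_taxa=10, region_layout=SMALL_LAYOUT,
                                       rate_multiplier=mult, indel_rate=0.0, seed=seed)
            world = generate_world(cfg)
            full = distance_matrix(world.truth_alignment, "one_gap")
            region = extract_region(world.truth_alignment, world.coordinate_map,
                                    RegionDef("var", 61, 90))
            sub = distance_matrix(region, "one_gap")
            xs, ys = matched_pairs(full, sub)
            try:
                slopes.append(regress_origin(xs, ys).slope_through_origin)
            except ValueError:
                continue
        mean_slopes.append(np.mean(slopes))
    assert mean_slopes[0] < mean_slopes[1] < mean_slopes[2]


def test_pipeline_smoke_emits_declared_outputs(tmp_path):
    from ssudiv.mocksim import MockDesign

    cfg = PipelineConfig(
        world=SyntheticWorldConfig(n_taxa=20, region_layout=SMALL_LAYOUT, seed=1),
        calculators=("one_gap", "each_gap"),
        regions=(("left", 5, 60), ("mid", 61, 90)),
        perturbations=("faithful", "shuffle_variable"),
        apply_lane_style_mask=True,
        out_dir=str(tmp_path / "run"),
    )
    bundle = run_pipeline(cfg)
    out = tmp_path / "run"
    for name in ("truth.fasta", "true_tree.nwk", "coordinate_map.tsv", "regressions.tsv",
                 "richness_full.tsv", "nj_tree.nwk", "mask.txt", "run_log.txt"):
        assert (out / name).exists(), name
    assert bundle["pd"] > 0
    assert not bundle["regressions"].empty
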
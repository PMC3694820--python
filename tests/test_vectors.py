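"""Quadrant assignment, polygon construction and GxE/GxG/GxGxE detection."""

import numpy as np
import pytest

from envepi.classify import classify_pair
from envepi.effects import compute_effects
from envepi.gpmap import ENV_0, ENV_1, ENVIRONMENTS
from envepi.simulate import generate_dataset, preset, random_two_locus_landscape
from envepi.vectors import (
    CLOSURE_TOL,
    build_polygon,
    detect_gxe,
    detect_gxg,
    detect_gxgxe,
    mutation_vector,
    polygon_census,
)

from conftest import make_two_locus_map
from test_classify import oracle_sign


def _map_and_effects(env0, env1):
    gpmap = make_two_locus_map(env0, env1)
    return gpmap, compute_effects(gpmap)


def test_neutral_in_both_environments_is_quadrant_III(flat_map):
    effects = compute_effects(flat_map)
    vec = mutation_vector(flat_map, "A", flat_map.variant.wildtype(), effects)
    assert vec.quadrant == "III"
    assert vec.zero_length
    assert not detect_gxe(vec)


def test_beneficial_in_both_environments_is_quadrant_I():
    gpmap, effects = _map_and_effects(
        {"": 1.0, "A": 4.0, "B": 1.0, "A;B": 4.0},
        {"": 1.0, "A": 0.25, "B": 1.0, "A;B": 0.25},
    )
    vec = mutation_vector(gpmap, "A", gpmap.variant.wildtype(), effects)
    assert vec.quadrant == "I"
    assert not detect_gxe(vec)


def test_env1_only_benefit_is_quadrant_II():
    """A lock-like mutation: strong expression drop under inducer only."""
    gpmap, effects = _map_and_effects(
        {"": 1.0, "A": 1.0, "B": 1.0, "A;B": 1.0},
        {"": 1.0, "A": 0.01, "B": 1.0, "A;B": 0.01},
    )
    vec = mutation_vector(gpmap, "A", gpmap.variant.wildtype(), effects)
    assert vec.quadrant == "II"
    assert detect_gxe(vec)


def test_quadrants_match_sign_oracle_on_random_landscapes():
    """Quadrant logic agrees with direct benefit-sign enumeration."""
    quadrant_of = {
        ("beneficial", "beneficial"): "I",
        ("deleterious", "beneficial"): "II",
        ("deleterious", "deleterious"): "III",
        ("beneficial", "deleterious"): "IV",
    }
    rng = np.random.default_rng(11)
    for _ in range(300):
        landscape = random_two_locus_landscape(rng)
        gpmap = generate_dataset(landscape).gpmap
        effects = compute_effects(gpmap)
        wt = gpmap.variant.wildtype()
        for mut, other in (("A", "B"), ("B", "A")):
            for bg_label, bg in (("", wt), (other, gpmap.variant.genotype([other]))):
                vec = mutation_vector(gpmap, mut, bg, effects)
                after = f"A;B" if bg_label else mut
                sx = oracle_sign(landscape.expression, ENV_0.label, bg_label, after)
                sy = oracle_sign(landscape.expression, ENV_1.label, bg_label, after)
                assert vec.quadrant == quadrant_of[(sx, sy)]


@pytest.mark.parametrize(
    "name, gxe, gxg, gxgxe",
    [
        ("parallelogram", False, False, False),
        ("gxe_only", True, False, False),
        ("gxg_only", False, True, False),
        ("gxgxe", True, True, True),
        ("figS1_counterexample", True, True, False),
    ],
)
def test_preset_interaction_flags(name, gxe, gxg, gxgxe):
    """The canonical motif presets show exactly the intended interactions;
    the counterexample shows GxE plus GxG is not sufficient for GxGxE."""
    gpmap = generate_dataset(preset(name)).gpmap
    effects = compute_effects(gpmap)
    poly = build_polygon(gpmap, "A", "B", gpmap.variant.wildtype(), effects)
    assert poly.has_gxe == gxe
    assert detect_gxg(poly) == gxg
    assert detect_gxgxe(poly) == gxgxe


def test_gxgxe_implies_gxg_on_random_landscapes():
    rng = np.random.default_rng(23)
    for _ in range(200):
        gpmap = generate_dataset(random_two_locus_landscape(rng)).gpmap
        poly = build_polygon(
            gpmap, "A", "B", gpmap.variant.wildtype(), compute_effects(gpmap)
        )
        if detect_gxgxe(poly):
            assert detect_gxg(poly)


def test_split_opposing_pair_implies_sign_epistasis_somewhere():
    """A split opposing pair means the pair is S or R in >= 1 environment."""
    rng = np.random.default_rng(31)
    for _ in range(200):
        gpmap = generate_dataset(random_two_locus_landscape(rng)).gpmap
        effects = compute_effects(gpmap)
        wt = gpmap.variant.wildtype()
        poly = build_polygon(gpmap, "A", "B", wt, effects)
        if detect_gxg(poly):
            cats = {
                classify_pair(gpmap, "A", "B", wt, env, effects).category
                for env in ENVIRONMENTS
            }
            assert cats & {"S", "R"}


def test_polygon_closure_exact(inversion_map_noise_free):
    effects = compute_effects(inversion_map_noise_free)
    v = inversion_map_noise_free.variant
    for rooting in ("absent", "present", "both"):
        census = polygon_census(inversion_map_noise_free, rooting, effects)
        for poly in census.polygons:
            assert poly.closure_error <= CLOSURE_TOL
    rng = np.random.default_rng(5)
    for _ in range(100):
        gpmap = generate_dataset(random_two_locus_landscape(rng)).gpmap
        poly = build_polygon(
            gpmap, "A", "B", gpmap.variant.wildtype(), compute_effects(gpmap)
        )
        assert poly.closure_error <= CLOSURE_TOL


def test_census_counts_three_variants(standin_maps):
    """Three 3-mutation variants give 3 polygons x 2 opposing pairs each
    under single-rooted counting, 18 opposing pairs in total."""
    total = 0
    for gpmap in standin_maps.values():
        census = polygon_census(gpmap.normalize(), rooting="present")
        assert census.n_polygons == 3
        assert census.n_opposing_pairs == 6
        total += census.n_opposing_pairs
    assert total == 18


def test_census_both_rooting_doubles_polygons(standin_maps):
    gpmap = next(iter(standin_maps.values())).normalize()
    assert polygon_census(gpmap, rooting="both").n_polygons == 6
    assert polygon_census(gpmap, rooting="absent").n_polygons == 3


def test_all_parallelogram_map_has_no_gxgxe_signature():
    census = polygon_census(
        generate_dataset(preset("parallelogram")).gpmap, rooting="both"
    )
    assert census.n_split == 0
    assert census.n_gxgxe == 0
    assert census.fraction_lacking_gxgxe_signature == 1.0


def test_inv1_narrated_rotation(standin_maps):
    """In the P97 background, adding T258A moves the R207L vector from
    quadrant III to IV (the narrated example of a GxGxE signature)."""
    gpmap = standin_maps["LacI_inv1"].normalize()
    effects = compute_effects(gpmap)
    v = gpmap.variant
    without = mutation_vector(gpmap, "R207L", v.genotype(["S97P"]), effects)
    with_t = mutation_vector(
        gpmap, "R207L", v.genotype(["S97P", "T258A"]), effects
    )
    assert (without.quadrant, with_t.quadrant) == ("III", "IV")
    poly = build_polygon(gpmap, "R207L", "T258A", v.genotype(["S97P"]), effects)
    assert detect_gxgxe(poly)


def test_inv2_narrated_rotation(standin_maps):
    """Adding L307H rotates the L349P vector from IV to II in the P97
    background: a sign change on both axes."""
    gpmap = standin_maps["LacI_inv2"].normalize()
    effects = compute_effects(gpmap)
    v = gpmap.variant
    without = mutation_vector(gpmap, "L349P", v.genotype(["S97P"]), effects)
    with_l = mutation_vector(
        gpmap, "L349P", v.genotype(["S97P", "L307H"]), effects
    )
    assert (without.quadrant, with_l.quadrant) == ("IV", "II")
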
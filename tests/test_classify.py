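"""M / S / R classification against brute-force sign-table oracles."""

import numpy as np
import pytest

from envepi.classify import classify_all, classify_pair, environment_concordance
from envepi.effects import compute_effects
from envepi.gpmap import ENV_0, ENV_1, ENVIRONMENTS, Genotype
from envepi.simulate import generate_dataset, random_two_locus_landscape

from conftest import make_two_locus_map

# ---------------------------------------------------------------------------
# independent oracle: benefit signs straight from noise-free true values
# ---------------------------------------------------------------------------

_POLARITY = {ENV_0.label: +1, ENV_1.label: -1}


def oracle_sign(truth, env_label, before_label, after_label):
    """beneficial iff the value changes in the favored direction."""
    v0, v1 = truth[env_label][before_label], truth[env_label][after_label]
    if v1 == v0:
        return "deleterious"
    went_up = v1 > v0
    favored_up = _POLARITY[env_label] > 0
    return "beneficial" if went_up == favored_up else "deleterious"


def oracle_category(truth, env_label, a="A", b="B"):
    """Enumerate the four signs of a two-locus landscape directly."""
    sa = oracle_sign(truth, env_label, "", a)
    sa_with = oracle_sign(truth, env_label, b, f"{a};{b}")
    sb = oracle_sign(truth, env_label, "", b)
    sb_with = oracle_sign(truth, env_label, a, f"{a};{b}")
    a_flips, b_flips = sa != sa_with, sb != sb_with
    if a_flips and b_flips:
        return ("R", None)
    if a_flips:
        return ("S", a)
    if b_flips:
        return ("S", b)
    return ("M", None)


def test_flat_landscape_all_magnitude(flat_map):
    table = classify_all(flat_map)
    assert len(table) == 1  # one pair, wild-type background only
    for motif in table.motifs:
        for env in ENVIRONMENTS:
            call = motif.calls[env.label]
            assert call.category == "M"


def test_flat_three_locus_panel_all_magnitude(inversion_map_noise_free):
    """A 3-mutation panel has exactly 6 motif rows."""
    table = classify_all(inversion_map_noise_free)
    assert len(table) == 6


def test_classify_pair_symmetry():
    rng = np.random.default_rng(7)
    for _ in range(50):
        gpmap = generate_dataset(random_two_locus_landscape(rng)).gpmap
        effects = compute_effects(gpmap)
        wt = gpmap.variant.wildtype()
        for env in ENVIRONMENTS:
            ab = classify_pair(gpmap, "A", "B", wt, env, effects)
            ba = classify_pair(gpmap, "B", "A", wt, env, effects)
            assert ab.category == ba.category
            assert ab.sign_changer == ba.sign_changer


def test_reciprocal_sign_epistasis_canonical():
    """Both deleterious alone, beneficial together: the valley pattern."""
    env0 = {"": 4.0, "A": 1.0, "B": 1.0, "A;B": 16.0}
    env1 = {"": 1.0, "A": 1.0, "B": 1.0, "A;B": 1.0}
    gpmap = make_two_locus_map(env0, env1)
    call = classify_pair(gpmap, "A", "B", gpmap.variant.wildtype(), ENV_0)
    assert call.category == "R"
    assert call.beneficial_together is True


def test_mirror_reciprocal_pattern_flagged():
    """Beneficial alone, deleterious together: labelled R with the
    orientation flag cleared (and a warning), not a fourth category."""
    env0 = {"": 1.0, "A": 4.0, "B": 4.0, "A;B": 0.25}
    env1 = {"": 1.0, "A": 1.0, "B": 1.0, "A;B": 1.0}
    gpmap = make_two_locus_map(env0, env1)
    call = classify_pair(gpmap, "A", "B", gpmap.variant.wildtype(), ENV_0)
    assert call.category == "R"
    assert call.beneficial_together is False


def test_sign_epistasis_names_the_changer():
    env0 = {"": 1.0, "A": 2.0, "B": 1.0, "A;B": 8.0}  # B neutral alone
    env1 = {"": 1.0, "A": 0.5, "B": 1.0, "A;B": 0.125}
    gpmap = make_two_locus_map(env0, env1)
    call = classify_pair(gpmap, "A", "B", gpmap.variant.wildtype(), ENV_0)
    assert (call.category, call.sign_changer) == ("S", "B")


def test_background_carrying_pair_mutation_rejected(inversion_map_noise_free):
    v = inversion_map_noise_free.variant
    with pytest.raises(ValueError, match="background"):
        classify_pair(
            inversion_map_noise_free, "L1", "D1", v.genotype(["L1"]), ENV_0
        )


def test_incomplete_map_error_lists_missing():
    env0 = {"": 1.0, "A": 2.0, "B": 1.0, "A;B": 8.0}
    env1 = {"": 1.0, "A": 0.5, "B": 1.0, "A;B": 0.125}
    gpmap = make_two_locus_map(env0, env1)
    # rebuild without the double mutant
    from envepi.gpmap import GenotypePhenotypeMap

    partial = GenotypePhenotypeMap(gpmap.variant)
    for rec in gpmap:
        if rec.genotype.bits != (1, 1):
            partial.add(rec)
    with pytest.raises(ValueError, match="A;B"):
        classify_all(partial)


def test_categories_match_oracle_on_random_landscapes():
    """Pipeline M/S/R equals direct sign enumeration, noise-free."""
    rng = np.random.default_rng(42)
    for _ in range(300):
        landscape = random_two_locus_landscape(rng)
        gpmap = generate_dataset(landscape).gpmap
        effects = compute_effects(gpmap)
        wt = gpmap.variant.wildtype()
        for env in ENVIRONMENTS:
            call = classify_pair(gpmap, "A", "B", wt, env, effects)
            want_cat, want_changer = oracle_category(
                landscape.expression, env.label
            )
            assert call.category == want_cat
            if want_cat == "S":
                assert call.sign_changer == want_changer


# -- concordance ------------------------------------------------------------


def test_fixture_concordance_nine_of_eighteen(fixture_table):
    n_same, n_total, discordant = environment_concordance(fixture_table)
    assert (n_same, n_total) == (9, 18)
    assert len(discordant) == 9


def test_inv2_panel_concordance(fixture_table):
    rows = fixture_table.for_variant("LacI_inv2")
    pairs = [(r.category_env0, r.category_env1) for r in rows]
    n_same, n_total, _ = environment_concordance(pairs)
    assert (n_same, n_total) == (2, 6)


def test_all_magnitude_table_fully_concordant(inversion_map_noise_free):
    table = classify_all(inversion_map_noise_free)
    n_same, n_total, discordant = environment_concordance(table)
    assert n_same == n_total and not discordant
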
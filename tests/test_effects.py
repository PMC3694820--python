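"""Directional effects: t-tests, Bonferroni, benefit signs, pooling."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from envepi.effects import (
    BENEFICIAL,
    DELETERIOUS,
    SignificancePolicy,
    compute_effects,
    correct_multiplicity,
    pooled_significance_override,
    t_test_effect,
)
from envepi.gpmap import ENV_0, ENV_1, ExpressionRecord, Genotype

from conftest import make_two_locus_map, summary_map

WT2 = Genotype((0, 0))


def rec(mean, sd, n=3, env=ENV_0):
    return ExpressionRecord(WT2, env, summary=(mean, sd, n))


def test_identical_records_not_significant():
    assert t_test_effect(rec(1.0, 0.1), rec(1.0, 0.1)) == pytest.approx(1.0)


def test_strong_separation_tiny_p():
    """Closed-form pooled-t oracle for a clearly separated contrast."""
    p = t_test_effect(rec(1.0, 0.01), rec(10.0, 0.01))
    # independent closed form: pooled t with n1 = n2 = 3, df = 4
    t = (10.0 - 1.0) / (0.01 * math.sqrt(2.0 / 3.0))
    p_oracle = 2.0 * stats.t.sf(t, df=4)
    assert p < 1e-6
    assert p == pytest.approx(p_oracle, rel=1e-9)


def test_summary_equals_replicates():
    reps = (0.9, 1.0, 1.1)
    m = sum(reps) / 3
    sd = math.sqrt(sum((v - m) ** 2 for v in reps) / 2)
    a = ExpressionRecord(WT2, ENV_0, replicates=reps)
    b = rec(2.0, 0.1)
    assert t_test_effect(a, b) == pytest.approx(
        t_test_effect(rec(m, sd), b), rel=1e-12
    )


def test_zero_spread_unequal_means_is_certain():
    assert t_test_effect(rec(1.0, 0.0), rec(2.0, 0.0)) == 0.0


def test_environment_mismatch_and_small_n_rejected():
    with pytest.raises(ValueError, match="environment"):
        t_test_effect(rec(1.0, 0.1, env=ENV_0), rec(1.0, 0.1, env=ENV_1))
    with pytest.raises(ValueError, match="n >= 2"):
        t_test_effect(rec(1.0, 0.1, n=1), rec(1.0, 0.1))


def test_welch_differs_from_pooled_with_unequal_variances():
    a, b = rec(1.0, 0.01, n=3), rec(1.5, 0.5, n=6)
    pooled = t_test_effect(a, b, SignificancePolicy(flavor="pooled"))
    welch = t_test_effect(a, b, SignificancePolicy(flavor="welch"))
    assert pooled != welch


@pytest.mark.parametrize(
    "pvals, alpha, expected",
    [
        ([0.04], 0.05, [True]),
        ([0.001] + [0.5] * 23, 0.05, [True] + [False] * 23),
        ([0.01] + [0.5] * 23, 0.05, [False] * 24),  # 0.01 > 0.05/24
    ],
)
def test_bonferroni_flags(pvals, alpha, expected):
    assert correct_multiplicity(pvals, alpha) == expected


def test_bonferroni_empty_family_errors():
    with pytest.raises(ValueError):
        correct_multiplicity([])


def _simple_map(wt_env0=1.0, mut_env0=2.0, wt_env1=1.0, mut_env1=2.0, cv=0.01):
    env0 = {"": wt_env0, "A": mut_env0, "B": wt_env0, "A;B": mut_env0}
    env1 = {"": wt_env1, "A": mut_env1, "B": wt_env1, "A;B": mut_env1}
    from envepi.gpmap import Variant

    return summary_map(Variant.from_names("v", ["A", "B"]),
                       {ENV_0.label: env0, ENV_1.label: env1}, cv=cv)


def test_benefit_polarity_per_environment():
    """Expression increase is beneficial without inducer, deleterious with."""
    gpmap = _simple_map(mut_env0=5.0, mut_env1=5.0)
    effects = compute_effects(gpmap)
    wt = gpmap.variant.wildtype()
    assert effects.get("A", wt, ENV_0).sign == BENEFICIAL
    assert effects.get("A", wt, ENV_1).sign == DELETERIOUS


def test_neutral_grouped_under_deleterious():
    gpmap = _simple_map(mut_env0=1.0, mut_env1=0.2)
    effects = compute_effects(gpmap)
    wt = gpmap.variant.wildtype()
    eff = effects.get("A", wt, ENV_0)
    assert not eff.significant and eff.sign == DELETERIOUS
    # the same mutation is beneficial in Env_1 (significant decrease)
    assert effects.get("A", wt, ENV_1).sign == BENEFICIAL


def test_beneficial_implies_significant():
    gpmap = _simple_map(mut_env0=3.0, mut_env1=0.5, cv=0.02)
    for eff in compute_effects(gpmap):
        if eff.sign == BENEFICIAL:
            assert eff.significant


@settings(max_examples=30, deadline=None)
@given(scale=st.floats(min_value=1e-3, max_value=1e3))
def test_signs_invariant_under_environment_rescaling(scale):
    """Rescaling all expression in one environment never flips a sign."""
    base = _simple_map(mut_env0=3.0, mut_env1=0.5)
    scaled = _simple_map(wt_env0=scale, mut_env0=3.0 * scale, mut_env1=0.5)
    signs = lambda g: {
        (e.mutation, e.background.bits, e.environment.label): e.sign
        for e in compute_effects(g)
    }
    assert signs(base) == signs(scaled)


def test_zero_noise_makes_every_nonzero_effect_significant():
    env0 = {"": 1.0, "A": 1.5, "B": 1.0, "A;B": 1.5}
    env1 = {"": 1.0, "A": 1.0, "B": 2.0, "A;B": 2.0}
    gpmap = make_two_locus_map(env0, env1)
    for eff in compute_effects(gpmap):
        assert eff.significant == (eff.fold_change != 1.0)


# -- cross-dataset pooling --------------------------------------------------


def _three_tables(folds, cv=0.02):
    """Three variant datasets sharing mutation A in the wild-type background,
    with the given Env_0 fold changes."""
    from envepi.gpmap import Variant

    tables = []
    for i, fold in enumerate(folds):
        env0 = {"": 1.0, "A": fold, "B": 1.0, "A;B": fold}
        env1 = {"": 1.0, "A": 0.5, "B": 1.0, "A;B": 0.5}
        gpmap = summary_map(
            Variant.from_names(f"v{i}", ["A", "B"]),
            {ENV_0.label: env0, ENV_1.label: env1},
            cv=cv,
        )
        tables.append(compute_effects(gpmap))
    return tables


def test_override_applied_with_majority():
    # significant in two datasets, marginal (non-significant) in the third
    tables = _three_tables([2.0, 2.0, 1.01])
    third = tables[2]
    wt = third.gpmap.variant.wildtype()
    assert not third.get("A", wt, ENV_0).significant
    assert pooled_significance_override(tables, "A", "", ENV_0)
    eff = third.get("A", wt, ENV_0)
    assert eff.significant and eff.sign == BENEFICIAL


def test_override_needs_multiple_datasets():
    tables = _three_tables([2.0])
    assert not pooled_significance_override(tables, "A", "", ENV_0)


def test_override_refused_on_conflicting_directions():
    tables = _three_tables([3.0, 0.3, 1.01])
    assert not pooled_significance_override(tables, "A", "", ENV_0)
    wt = tables[2].gpmap.variant.wildtype()
    assert not tables[2].get("A", wt, ENV_0).significant
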
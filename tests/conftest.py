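import dataclasses

import pytest

from envepi.examples import synthetic_expression_tables
from envepi.gpmap import (
    ENV_0,
    ENV_1,
    ENVIRONMENTS,
    ExpressionRecord,
    GenotypePhenotypeMap,
    Variant,
    load_table1_fixture,
)
from envepi.simulate import ExplicitLandscape, generate_dataset, preset


@pytest.fixture(scope="session")
def fixture_table():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def standin_maps():
    """Synthetic summary-statistics maps for the three inverse variants."""
    return synthetic_expression_tables()


@pytest.fixture(scope="session")
def inversion_map_noise_free():
    """The thermodynamic inversion preset with replicate noise switched off."""
    params = dataclasses.replace(preset("inversion"), noise_cv=0.0)
    return generate_dataset(params).gpmap.normalize()


def make_two_locus_map(env0, env1, names=("A", "B"), noise_cv=0.0, seed=0):
    """Explicit two-locus map from {genotype label: value} dicts per env."""
    landscape = ExplicitLandscape(
        mutation_names=tuple(names),
        expression={ENV_0.label: env0, ENV_1.label: env1},
        noise_cv=noise_cv,
        seed=seed,
    )
    return generate_dataset(landscape).gpmap


@pytest.fixture()
def flat_map():
    """Two-locus landscape with identical expression everywhere."""
    flat = {"": 1.0, "A": 1.0, "B": 1.0, "A;B": 1.0}
    return make_two_locus_map(flat, dict(flat))


def summary_map(variant: Variant, means: dict, cv=0.02, n=3):
    """Summary-mode map from {env label: {genotype label: mean}}."""
    gpmap = GenotypePhenotypeMap(variant)
    for env in ENVIRONMENTS:
        for label, mean in means[env.label].items():
            genotype = variant.genotype([t for t in label.split(";") if t])
            gpmap.add(
                ExpressionRecord(genotype, env, summary=(mean, cv * mean, n))
            )
    return gpmap
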
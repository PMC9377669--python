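"""Shared fixtures: packaged screen counts and small synthetic screens."""

import pytest

from teratoclass import synthetic_data as sd


@pytest.fixture(scope="session")
def table2():
    return sd.table2_fixture()


def _tiny_config(seed: int = 5) -> sd.SyntheticConfig:
    """Fast 4-compound screen with a shared teratogen program (300 probes)."""
    effect = sd.EffectSpec(mean_abs_log2fc=1.5, sd_log2fc=0.2)
    compounds = tuple(
        sd.CompoundSpec(
            compound_id=f"tox{i}", label="teratogen",
            n_affected_probesets=40, effect_log2fc=effect, signature_frac=0.8,
        )
        for i in range(3)
    ) + tuple(
        sd.CompoundSpec(
            compound_id=f"neg{i}", label="non_teratogen",
            n_affected_probesets=2,
            effect_log2fc=sd.EffectSpec(mean_abs_log2fc=0.4),
        )
        for i in range(3)
    )
    return sd.SyntheticConfig(
        compounds=compounds, n_probesets=300, signature_pool_size=50,
        n_batches=2, seed=seed,
    )


@pytest.fixture(scope="session")
def tiny_config():
    return _tiny_config()


@pytest.fixture(scope="session")
def tiny_screen(tiny_config):
    """(matrix, sheet, annotations) of the fast screen."""
    return sd.generate_screen(tiny_config)
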
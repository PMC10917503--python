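import numpy as np
import pytest

from phytoclock import (
    KnockoutMode,
    LightProtocol,
    SplitCoupling,
    classify_rhythmicity,
    load_base_parameters,
    parameters_for_variant,
    parse_genotype,
    run_simulation,
)


@pytest.fixture(scope="session")
def base_params():
    return load_base_parameters()


@pytest.fixture(scope="session")
def default_protocol():
    return LightProtocol()


@pytest.fixture(scope="session")
def short_protocol():
    """Cheap protocol for structural/numerical tests."""
    return LightProtocol(entrain_days=2, free_run_days=1)


@pytest.fixture(scope="session")
def sim(base_params, default_protocol):
    """Session-cached simulation factory keyed by (variant, genotype, mode, coupling)."""
    cache = {}

    def factory(
        variant: str,
        genotype: str = "WT",
        mode: KnockoutMode = KnockoutMode.BASAL_AND_LIGHT,
        coupling: SplitCoupling = SplitCoupling.SUM_HALVED,
    ):
        key = (variant, genotype, mode, coupling)
        if key not in cache:
            params = parameters_for_variant(variant, base_params, coupling=coupling)
            cache[key] = run_simulation(
                variant,
                params,
                genotype=parse_genotype(genotype),
                protocol=default_protocol,
                knockout_mode=mode,
                coupling=coupling,
            )
        return cache[key]

    return factory


@pytest.fixture(scope="session")
def classify_component():
    """Classify one free-run component of a trajectory, matrix-style."""

    def classify(traj, component: str):
        fr = traj.free_run()
        entrained = traj.component(component)[traj.time_h < traj.release_time_h]
        ref = float(np.max(entrained) - np.min(entrained))
        return classify_rhythmicity(
            fr.time_h,
            fr.component(component),
            component=component,
            reference_range=ref,
            ct_offset_h=traj.release_time_h,
        )

    return classify
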
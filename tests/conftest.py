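import numpy as np
import pytest

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "ci",
        derandomize=True,
        deadline=None,
        max_examples=25,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def mid_ensemble():
    """Six-replicate ABM ensemble at the central parameter vector."""
    from smoreglos import ABMParams, run_ensemble

    return run_ensemble(ABMParams(), n_replicates=6, base_seed=3)


@pytest.fixture(scope="session")
def mid_cellcycle_fit(mid_ensemble):
    from smoreglos import CellCycleModel, fit_sm

    model = CellCycleModel()
    return model, fit_sm(model, mid_ensemble, seed=0)
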
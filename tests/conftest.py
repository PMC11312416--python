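import numpy as np
import pytest

from cryopvi import RunConfig, load_packaged_logs


@pytest.fixture(scope="session")
def packaged_logs():
    return load_packaged_logs()


@pytest.fixture(scope="session")
def coarse_config():
    """Cheap configuration for end-to-end plumbing tests (not accuracy)."""
    return RunConfig(cell_size_mm=0.6, timestep_s=0.5, snapshot_interval_s=30.0)


@pytest.fixture(scope="session")
def coarse_run(coarse_config, packaged_logs):
    """One coarse patient-1 therapy run shared across tests."""
    from cryopvi.protocol import build_schedule
    from cryopvi.solver import run_therapy

    domain = coarse_config.build_domain()
    schedule = build_schedule(packaged_logs[0],
                              coarse_config.rewarm_duration_s)
    history = run_therapy(domain, schedule, coarse_config.solver_config())
    return domain, schedule, history
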
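import numpy as np
import pytest

from taskrel import (
    AcquisitionSpec,
    EffectTopology,
    PipelineConfig,
    Region,
    generate_schedule,
    run_pipeline,
)


@pytest.fixture(scope="session")
def schedule():
    return generate_schedule("eye-movement", "forward")


@pytest.fixture(scope="session")
def acq():
    return AcquisitionSpec()


def cube_topology(acq: AcquisitionSpec, n_regions: int = 8, size: int = 2, mu: float = 1.0):
    """Disjoint cubic regions tiled through the grid, conditions cycled.

    Each region gets independent amplitude draws in the simulator, so map
    summaries average over independent realizations of the reliability
    process.
    """
    conditions = ("auditory", "visual", "motor", "cognitive")
    shape = acq.grid_shape
    regions = []
    per_axis = max(s // (size + 1) for s in shape)
    idx = 0
    for i in range(0, shape[0] - size, size + 1):
        for j in range(0, shape[1] - size, size + 1):
            for k in range(0, shape[2] - size, size + 1):
                if idx >= n_regions:
                    break
                mask = np.zeros(shape, bool)
                mask[i : i + size, j : j + size, k : k + size] = True
                regions.append(
                    Region(name=f"r{idx}", mask=mask, condition=conditions[idx % 4], mu=mu)
                )
                idx += 1
    assert len(regions) == n_regions, "grid too small for requested regions"
    return EffectTopology(regions=tuple(regions))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full default-config pipeline run, shared across tests."""
    out = tmp_path_factory.mktemp("default_run")
    cfg = PipelineConfig()
    report = run_pipeline(cfg, out)
    return cfg, report
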
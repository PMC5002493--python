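"""Shared session fixtures: the expensive simulations are run once and
inspected by several acceptance tests."""

import numpy as np
import pytest


@pytest.fixture(scope="session")
def cylinder_re40():
    from pinchflow.experiments import (CylinderBenchmarkConfig,
                                       run_cylinder_benchmark)

    cfg = CylinderBenchmarkConfig(Re=40, resolution_scale=0.5,
                                  max_steps=40000)
    return run_cylinder_benchmark(cfg)


@pytest.fixture(scope="session")
def cylinder_re100():
    from pinchflow.experiments import (CylinderBenchmarkConfig,
                                       run_cylinder_benchmark)

    cfg = CylinderBenchmarkConfig(Re=100, resolution_scale=0.5,
                                  max_steps=70000)
    return run_cylinder_benchmark(cfg)
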
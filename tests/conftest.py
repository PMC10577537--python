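import numpy as np
import pytest

import isectclock as ic


@pytest.fixture(scope="session")
def small_spec():
    return ic.GeneratorSpec(n_samples=30, n_sites=300, n_informative=60, rng_seed=11)


@pytest.fixture(scope="session")
def small_table(small_spec):
    return ic.training_feature_table(small_spec)


@pytest.fixture(scope="session")
def small_config():
    return ic.ClockConfig(min_intersection=50, rng_seed=11)


@pytest.fixture
def write_report(tmp_path):
    """Write raw CpG-report lines to a temp file and return its path."""

    def _write(lines, name="sample.CpG_report.txt"):
        path = tmp_path / name
        path.write_text("".join(line + "\n" for line in lines))
        return path

    return _write
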
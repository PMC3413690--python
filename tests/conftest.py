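import numpy as np
import pytest

from averted.life_tables import AbridgedLifeTable
from averted.synthetic import GeneratorConfig, make_baseline, make_catalogue


@pytest.fixture(scope="session")
def gen_cfg() -> GeneratorConfig:
    return GeneratorConfig(seed=0)


@pytest.fixture(scope="session")
def baseline(gen_cfg):
    """(life table, burden, fertility) for the default synthetic baseline."""
    return make_baseline(gen_cfg)


@pytest.fixture(scope="session")
def catalogue(gen_cfg):
    return make_catalogue(gen_cfg)


def make_uniform_table(n: int = 100, a_x: float = 0.5) -> AbridgedLifeTable:
    """1/n of the radix dying in each of n one-year intervals (plus an empty
    open terminal interval)."""
    age_start = np.arange(n + 1, dtype=float)
    width = np.concatenate((np.ones(n), [np.inf]))
    deaths = np.concatenate((np.full(n, 100_000.0 / n), [0.0]))
    a = np.concatenate((np.full(n, a_x), [np.nan]))
    return AbridgedLifeTable(age_start=age_start, width=width, deaths=deaths, a_x=a)


def make_constant_hazard_table(
    m: float = 0.02, width: float = 0.1, n: int = 2000
) -> AbridgedLifeTable:
    """Fine-grid table for exponential survival with hazard m; the open
    terminal interval keeps the memoryless expectancy 1/m."""
    starts = np.arange(n, dtype=float) * width
    surv = np.exp(-m * starts)
    surv_next = np.exp(-m * (starts + width))
    deaths = 100_000.0 * (surv - surv_next)
    age_start = np.concatenate((starts, [n * width]))
    widths = np.concatenate((np.full(n, width), [np.inf]))
    deaths = np.concatenate((deaths, [100_000.0 * np.exp(-m * n * width)]))
    a = np.concatenate((np.full(n, 0.5), [np.nan]))
    return AbridgedLifeTable(
        age_start=age_start, width=widths, deaths=deaths, a_x=a,
        terminal_expectancy=1.0 / m,
    )
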
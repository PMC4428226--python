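import numpy as np
import pytest

from methpat import ErrorModel, PatternCounts, PatternDistribution, table1_fixture, table2_fixture


@pytest.fixture(scope="session")
def table1():
    """(true theta, counts, model) for the n=6 synthetic benchmark."""
    return table1_fixture()


@pytest.fixture(scope="session")
def table2():
    """(counts, model) for the n=8 honey-bee amplicon benchmark."""
    return table2_fixture()


@pytest.fixture(scope="session")
def table1_fast(table1):
    from methpat import estimate_fast

    _, counts, model = table1
    return estimate_fast(counts, model)


@pytest.fixture(scope="session")
def table1_slow(table1):
    from methpat import estimate_slow

    _, counts, model = table1
    return estimate_slow(counts, model)


@pytest.fixture(scope="session")
def table2_fast(table2):
    from methpat import estimate_fast

    counts, model = table2
    return estimate_fast(counts, model)


@pytest.fixture
def rng():
    return np.random.default_rng(20150506)


def random_counts(rng, n, n_patterns, n_read=500):
    """A random count table over distinct patterns at n CpG sites."""
    idx = rng.choice(2**n, size=min(n_patterns, 2**n), replace=False)
    y = rng.multinomial(n_read, np.ones(idx.size) / idx.size)
    pats = {format(k, f"0{n}b"): int(c) for k, c in zip(idx, y) if c > 0}
    return PatternCounts(n, pats)
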
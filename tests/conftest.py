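import numpy as np
import pytest

from protcur import fixtures as fx


@pytest.fixture(scope="session")
def worked_examples():
    return fx.worked_example_records()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def build_fixture_pool(seed: int = 7, n_families: int = 4, n_unrelated: int = 20):
    """The standard planted curation pool: per family 2 duplicates, 1
    fragment, 1 precursor variant and 2 point-mutation variants."""
    gen = np.random.default_rng(seed)
    fams = []
    for i in range(n_families):
        seed_seq = fx.random_protein(int(gen.integers(120, 240)), gen)
        fams.append(
            fx.make_family(
                seed_seq,
                n_duplicates=2,
                n_fragments=1,
                n_precursor_variants=1,
                n_variants=2,
                rng=gen,
                acc_offset=100 * i,
                family_label=f"FAM{i + 1}",
            )
        )
    return fx.make_pool(fams, n_unrelated=n_unrelated, rng=gen)


@pytest.fixture(scope="session")
def fixture_pool():
    return build_fixture_pool()
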
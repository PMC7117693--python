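import dataclasses

import pytest

from epicesdif import (eap_scores, fit_grm, generate_cohort,
                       india_like_preset, reverse_items)


@pytest.fixture(scope="session")
def nodif10():
    """Clean 10-item cohort: no DIF, no impact, no dependent pair; aligned
    coding (items 1 and 5 reversed). Returns (matrix, truth)."""
    cfg = india_like_preset(n_items=10, dif=False, impact=False,
                            dependent_pair=False)
    m, truth = generate_cohort(cfg)
    return reverse_items(m, [1, 5]), truth


@pytest.fixture(scope="session")
def fitted10(nodif10):
    """(bank, theta) from the clean cohort."""
    m, _ = nodif10
    bank = fit_grm(m)
    return bank, eap_scores(m, bank)


@pytest.fixture(scope="session")
def preset_full():
    """Full preset: DIF + impact + dependent pair, aligned coding."""
    m, truth = generate_cohort(india_like_preset())
    return reverse_items(m, [1, 5]), truth


@pytest.fixture()
def small_sim():
    """Small 2-group config factory for targeted simulations."""
    base = india_like_preset(n_items=10, dif=False, impact=False,
                             dependent_pair=False)

    def make(n_per_group=300, seed=0, **kw):
        return dataclasses.replace(
            base, group_sizes={"A": n_per_group, "B": n_per_group},
            seed=seed, **kw)

    return make
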
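import numpy as np
import pandas as pd
import pytest

from raschshort import pcm, synthetic as syn


@pytest.fixture(scope="session")
def uni800():
    """Fitted strictly unidimensional dataset: n=800, 12 five-category
    items, theta ~ N(0,1)."""
    rm = syn.simulate_unidimensional_pcm(
        syn.SyntheticSpec(n_persons=800, person_mean=0.0, person_sd=1.0, seed=11)
    )
    items = pcm.fit_items_cml(rm)
    persons = pcm.estimate_persons(rm, items)
    return rm, items, persons


@pytest.fixture(scope="session")
def bat800():
    """BAT-like four-subscale dataset (general + subscale nuisance factors)."""
    return syn.simulate_bat_like(syn.SyntheticSpec(n_persons=800, seed=11))


def make_response_matrix(X, item_ids=None, subscale=None, factors=None):
    """Small helper for hand-built score matrices."""
    X = np.asarray(X, dtype=int)
    ids = item_ids or [f"I{i+1}" for i in range(X.shape[1])]
    scores = pd.DataFrame(X, columns=ids)
    pf = factors if factors is not None else pd.DataFrame(index=scores.index)
    sub = subscale or {i: "S" for i in ids}
    return pcm.ResponseMatrix(scores=scores, person_factors=pf, subscale_map=sub)
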
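import itertools

import pandas as pd
import pytest

from vgckit import RatingPanel, SyntheticConfig, generate_panel


def build_panel(rating_fn, observers, cases, protocols, criteria, n_categories=5):
    """Complete panel whose rating for each cell is rating_fn(o, c, p, q)."""
    rows = [
        {
            "observer": o,
            "case": c,
            "protocol": p,
            "criterion": q,
            "rating": rating_fn(o, c, p, q),
        }
        for o, c, p, q in itertools.product(observers, cases, protocols, criteria)
    ]
    return RatingPanel(pd.DataFrame(rows), n_categories=n_categories)


@pytest.fixture
def identical_panel():
    """Two protocols rated identically for every (observer, case, criterion)."""
    return build_panel(
        lambda o, c, p, q: (sum(map(ord, c + q)) % 5) + 1,
        observers=["o1", "o2"],
        cases=[f"c{i}" for i in range(12)],
        protocols=["ref", "test"],
        criteria=["Q1", "Q2", "Q3"],
    )


@pytest.fixture
def study_panel():
    """Study-sized synthetic panel: 4 observers x 50 cases x 3 protocols x 14 criteria."""
    return generate_panel(SyntheticConfig(seed=42))
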
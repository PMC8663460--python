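import numpy as np
import pytest

import nvafsurv as nv


@pytest.fixture(scope="session")
def lex():
    return nv.default_lexicon()


@pytest.fixture(scope="session")
def hier():
    return nv.default_hierarchy()


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded 400-patient cohort shared by phenotype/score tests."""
    cfg = nv.SimConfig(n_patients=400, seed=11)
    return nv.generate_cohort(cfg)


def brute_force_match(token_texts: list[str], entries: dict) -> list[tuple]:
    """Independent longest-match oracle.

    Enumerates every subspan that is a lexicon term, then repeatedly selects
    the hit with the leftmost start, longest there (ties broken by smallest
    (system, code)), discarding overlapping hits.
    ``entries`` maps token-tuples to sorted [(system, code), ...].
    Returns [(start, end, system, code), ...].
    """
    hits = []
    n = len(token_texts)
    for i in range(n):
        for j in range(i + 1, n + 1):
            key = tuple(t.casefold() for t in token_texts[i:j])
            for system, code in entries.get(key, []):
                hits.append((i, j, system, code))
    chosen = []
    while hits:
        start = min(h[0] for h in hits)
        at = [h for h in hits if h[0] == start]
        at.sort(key=lambda h: (-(h[1] - h[0]), h[2], h[3]))
        best = at[0]
        chosen.append(best)
        hits = [h for h in hits if h[0] >= best[1]]
    return chosen
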
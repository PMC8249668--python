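"""Shared test utilities: vote-simulation oracle and generators."""

import numpy as np


def brute_force_majority(hard: np.ndarray) -> int:
    """Independent majority-vote oracle: count one-hot votes, break ties by
    the fixed class priority positive > neutral > negative."""
    tally = hard.sum(axis=0)
    best = tally.max()
    return next(c for c in (0, 2, 1) if tally[c] == best)


def simulate_asymmetric_votes(n: int, rng: np.random.Generator, m: int = 5):
    """Planted asymmetric reliability: model 0 votes class 0 correctly 80% of
    the time but is uninformative elsewhere; the rest are weak everywhere."""
    y = rng.choice(3, size=n, p=[0.34, 0.33, 0.33])
    votes = np.zeros((n, m, 3))
    for i, c in enumerate(y):
        v0 = 0 if (c == 0 and rng.random() < 0.8) else rng.choice(3)
        votes[i, 0, v0] = 1.0
        for j in range(1, m):
            vj = c if rng.random() < 0.45 else rng.choice([k for k in range(3) if k != c])
            votes[i, j, vj] = 1.0
    return votes, y
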
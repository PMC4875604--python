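import numpy as np
import pytest

from motifbench.motifs import PositionFrequencyMatrix, ScoringMatrix, to_scoring_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def consensus_matrix(pattern: str, strong: float = 100.0) -> ScoringMatrix:
    """Scoring matrix demanding an exact base pattern (weight ``strong`` on
    the pattern base, 0 elsewhere)."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    weights = np.zeros((4, len(pattern)))
    for j, b in enumerate(pattern):
        weights[idx[b], j] = strong
    return ScoringMatrix(tf_name=f"demand_{pattern}", weights=weights)


def pfm_from_probs(probs, name="tf", source="SYNTHETIC") -> PositionFrequencyMatrix:
    return PositionFrequencyMatrix(tf_name=name, probs=np.asarray(probs, float), source=source)


@pytest.fixture
def ac_matrix():
    """Width-2 matrix whose consensus is 'AC' with max score 200."""
    return consensus_matrix("AC")
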
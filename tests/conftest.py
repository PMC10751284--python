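import numpy as np
import pandas as pd
import pytest

import litaffect as la


@pytest.fixture(scope="session")
def small_null_corpus():
    """All-null synthetic corpus: 150 authors x 200 words, no injected effects."""
    spec = la.EffectSpec(vocab_size=200, n_authors=150, seed=11)
    return la.generate_corpus(spec)


@pytest.fixture(scope="session")
def effect_corpus():
    """Corpus with a strong main-effect word, a female-preferred word, and a
    pure interaction word (sex gap crossing zero at mid-period)."""
    span = 2020 - 1719
    spec = la.EffectSpec(
        vocab_size=60,
        n_authors=400,
        sex_effect_words={3: 0.8, 7: -0.8},
        interaction_words={12: 1.6 / span},
        seed=21,
    )
    return la.generate_corpus(spec)


@pytest.fixture()
def tiny_norms():
    return pd.DataFrame(
        {
            "word": ["alpha", "beta", "gamma", "delta"],
            "valence_m": [7.0, 3.0, 5.0, 6.0],
            "valence_f": [8.0, 2.0, 5.5, 6.5],
            "arousal_m": [4.0, 6.0, 5.0, 3.0],
            "arousal_f": [4.5, 5.5, 5.2, 3.2],
        }
    )


def male_mask(authors: pd.DataFrame) -> np.ndarray:
    return (authors["sex"] == "male").to_numpy()
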
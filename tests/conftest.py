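import numpy as np
import pytest

from gramnas.grammar import load_default_grammar, parse_grammar

# Small value domains so evolved networks stay desk-sized.
MICRO_GRAMMAR_TEXT = """
<topology> ::= <input> <conv-layers> <dense-layers> <learning>
<input> ::= batch <batch-size> window <window-size> step <window-step>
<batch-size> ::= 25 | 50
<window-size> ::= 8 | 16
<window-step> ::= 2
<conv-layers> ::= <conv> | <conv> <conv>
<conv> ::= conv <kernels> <kernel-size> <pooling> <activation>
<kernels> ::= 4 | 8
<kernel-size> ::= 2 | 3
<pooling> ::= 1 | 2
<activation> ::= linear | relu
<dense-layers> ::= <dense>
<dense> ::= dense <dense-type> <units> <dropout> <activation> <regularizer>
<dense-type> ::= feedforward | lstm | gru
<units> ::= 8 | 16
<dropout> ::= 0.0
<regularizer> ::= none
<learning> ::= optimizer <optimizer> rate <learning-rate>
<optimizer> ::= adam | rmsprop
<learning-rate> ::= 0.001
"""


@pytest.fixture(scope="session")
def grammar():
    return load_default_grammar()


@pytest.fixture(scope="session")
def micro_grammar():
    return parse_grammar(MICRO_GRAMMAR_TEXT)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def normalized_splits(frame, train_fraction=0.7):
    """Interpolate, split by timestep, min-max normalize with train stats."""
    from dataclasses import replace

    from gramnas.preprocess import compute_norm_stats, interpolate_missing, normalize

    frame = interpolate_missing(frame)
    T = frame.n_timesteps
    cut = int(T * train_fraction)

    def _slice(lo, hi):
        return replace(
            frame,
            values=frame.values[lo:hi],
            mask=frame.mask[lo:hi],
            labels=frame.labels[lo:hi],
        )

    train, val = _slice(0, cut), _slice(cut, T)
    stats = compute_norm_stats(train)
    return normalize(train, stats), normalize(val, stats, clip=True)
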
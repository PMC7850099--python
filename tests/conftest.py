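import numpy as np
import pytest

from genoshare.engine import run_two_party
from genoshare.sharing import ProtocolConfig, arith_share, bool_share


@pytest.fixture
def cfg32():
    return ProtocolConfig(l=32, rng_seed=1)


@pytest.fixture
def cfg4():
    return ProtocolConfig(l=4, rng_seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def eval_bool_gate(fn_name, plain_inputs, l, width, seed=0, triple_words=None,
                   config=None):
    """Share plaintext inputs, run one gate for both parties, reconstruct.

    ``plain_inputs`` is a list of plaintext word arrays; the gate method
    named ``fn_name`` is called with the corresponding BoolShareVectors.
    """
    config = config or ProtocolConfig(l=l, rng_seed=seed)
    rng = np.random.default_rng(seed)
    n = len(plain_inputs[0])
    shared = [bool_share(np.asarray(x, dtype=np.uint64), w, rng)
              for x, w in zip(plain_inputs, width)]
    ins0 = [s[0] for s in shared]
    ins1 = [s[1] for s in shared]
    words = triple_words if triple_words is not None else 80 * n + 64

    def program(rt, inputs):
        return getattr(rt, fn_name)(*inputs)

    out0, out1, rt0, rt1 = run_two_party(
        program, ins0, ins1, config=config, triple_words=words, dealer_seed=seed + 1
    )
    return (out0.bits ^ out1.bits), rt0, rt1
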
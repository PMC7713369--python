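import pytest

import reactioncode as rc


def corpus(seed, n, **spec):
    """n (reaction, ground truth) pairs with per-index shape variation."""
    out = []
    for k in range(n):
        out.append(rc.make_reaction(
            seed + k,
            center_size=2 + k % 3,
            remaining_depth=1 + k % 3,
            leaving_size=spec.get("leaving_size", k % 3),
            n_charges=k % 2,
            n_isotopes=(k // 3) % 2,
            n_radicals=(k // 5) % 2,
            n_stereo_bonds=spec.get("n_stereo_bonds", 0),
            aromatic=spec.get("aromatic", False),
            spectators=spec.get("spectators", 0),
        ))
    return out


@pytest.fixture(scope="session")
def mixed_corpus():
    """100 reactions mixing balanced/unbalanced shapes and decorations."""
    return corpus(20_000, 100)


@pytest.fixture(scope="session")
def examples():
    return rc.worked_examples()
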
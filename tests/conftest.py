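import pytest

import rnaloops as rl


@pytest.fixture(scope="session")
def figure1():
    return rl.fixture_figure1()


@pytest.fixture(scope="session")
def figure3():
    return rl.fixture_figure3()


@pytest.fixture(scope="session")
def figure1_ann(figure1):
    return rl.annotate(figure1)


@pytest.fixture(scope="session")
def figure3_ann(figure3):
    return rl.annotate(figure3)


@pytest.fixture(scope="session")
def named_fixture_anns():
    return {
        name: rl.annotate(rl.FIXTURES[name]())
        for name in ("hknot", "kissing", "tripleknot")
    }


def random_structures(n, length, n_stems, pk_prob, seed0, **kw):
    """Seeded stream of generated structures (skips infeasible draws)."""
    out = []
    seed = seed0
    while len(out) < n:
        try:
            out.append(
                rl.generate(
                    rl.GeneratorConfig(
                        length=length,
                        n_stems=n_stems,
                        pk_prob=pk_prob,
                        seed=seed,
                        **kw,
                    )
                )
            )
        except rl.GeneratorError:
            pass
        seed += 1
    return out
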
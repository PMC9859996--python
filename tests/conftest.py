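import pytest


@pytest.fixture(scope="session")
def desk_benchmark_table():
    """Seeded CPU-scale ablation benchmark shared by the end-to-end
    assertions: trains the gated model and the tumor-only baseline on
    200 synthetic 64x64 phantoms (half lesion-free) for 15 epochs and
    evaluates both on a held-out set of 60 phantoms.
    """
    from busgate.experiments import run_desk_benchmark
    return run_desk_benchmark(seed=0)
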
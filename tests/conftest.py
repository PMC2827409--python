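import numpy as np
import pytest

from finishassay import (
    BiasModel,
    BiasRegion,
    FinishedSequence,
    build_draft,
    generate_reference,
    simulate_shotgun,
)


@pytest.fixture(scope="session")
def small_ref():
    """A 60 kb plain reference (no planted features), fixed seed."""
    ref, ann = generate_reference(60_000, gc_target=0.45, seed=101)
    assert not ann.intervals
    return ref


@pytest.fixture(scope="session")
def biased_assembly(small_ref):
    """Draft assembly of the small reference with two zero-viability troughs."""
    bias = BiasModel(
        [BiasRegion(20_000, 22_500, 0.0), BiasRegion(40_000, 41_500, 0.0)]
    )
    pairs = simulate_shotgun(small_ref, redundancy=10, bias=bias, seed=7)
    draft, truth = build_draft(
        small_ref, pairs, min_contig=2000, shuffle=True, bias=bias, seed=13
    )
    return {"pairs": pairs, "draft": draft, "truth": truth, "bias": bias}


def random_placed_intervals(rng, length, n, max_span=5000):
    """Disjoint random intervals on [0, length)."""
    cuts = np.sort(rng.choice(length, size=min(2 * n, length // 2), replace=False))
    out = []
    for i in range(0, len(cuts) - 1, 2):
        s, e = int(cuts[i]), int(min(cuts[i + 1], cuts[i] + max_span))
        if e > s:
            out.append((s, e))
    return out
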
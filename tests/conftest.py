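import numpy as np
import pytest
from hypothesis import settings

from mitochip import probe_design, synthetic_data

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def genome_pair():
    """Deterministic synthetic genome pair with known ortholog structure."""
    return synthetic_data.gen_genome_pair(seed=1)


@pytest.fixture(scope="session")
def designed_probe_set(genome_pair):
    rec_a, rec_b, editing_b, _ = genome_pair
    return probe_design.design_probe_set(rec_a, rec_b, editing_b=editing_b)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def oracle_best_window(seq_a: str, seq_b: str, c: probe_design.DesignConstraints):
    """Exhaustive brute-force probe search on equal-length ortholog pairs.

    Independent of the designer: plain Python loops, direct formula
    evaluation, same tie-break order (score, fewer mismatches, longer
    window, smaller species-B offset).  Returns (key, species-B window)
    or None when no window is feasible.
    """
    assert len(seq_a) == len(seq_b)
    best = None
    for length in range(c.min_len, c.max_len + 1):
        for off in range(len(seq_b) - length + 1):
            wa = seq_a[off : off + length]
            wb = seq_b[off : off + length]
            mism = [i for i in range(length) if wa[i] != wb[i]]
            if len(mism) > c.max_mismatches:
                continue
            gc = (wb.count("G") + wb.count("C")) / length
            penalty = sum(
                1 - 2 * abs(i / (length - 1) - 0.5) for i in mism
            )
            score = c.weight_gc * abs(gc - c.gc_target) + c.weight_pos * penalty
            key = (score, len(mism), -length, off)
            if best is None or key < best[0]:
                best = (key, wb)
    return best
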
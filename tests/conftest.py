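import numpy as np
import pytest

from rhythmix import TimecourseMatrix

TIMES = (3.0, 7.0, 11.0, 15.0, 19.0, 23.0)


def make_matrix(values, condition="cond", times=TIMES, gene_ids=None, mask=None):
    """Wrap a (genes x samples) array as a TimecourseMatrix, inferring an
    equal replicate count per timepoint from the column count."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_t = len(times)
    assert values.shape[1] % n_t == 0
    reps = values.shape[1] // n_t
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    return TimecourseMatrix(
        gene_ids=list(gene_ids),
        condition=condition,
        times_h=np.asarray(times, dtype=float),
        n_replicates=np.full(n_t, reps, dtype=int),
        values=values,
        missing_mask=mask,
    )


def cosine_series(mu, amp, phase, times=TIMES, reps=3, period=24.0):
    """Noise-free oscillator values, timepoint-major with `reps` replicates."""
    t = np.repeat(np.asarray(times, dtype=float), reps)
    return mu * (1.0 + amp * np.cos(2.0 * np.pi * (t - phase) / period))


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(7)
    vals = rng.lognormal(2.0, 0.5, size=(5, 18))
    return make_matrix(vals)
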
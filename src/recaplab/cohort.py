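"""Cohort-level bookkeeping for organoid biobanks."""

from __future__ import annotations


def establishment_rate(n_established: int, n_samples: int) -> float:
    """Long-term establishment success rate, as a percentage of samples.

    A line counts as established only after stable expansion over the
    passage threshold and successful regrowth from a thawed stock; the rate
    is lines-from-distinct-patients over all samples received.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if not 0 <= n_established <= n_samples:
        raise ValueError("n_established must be in [0, n_samples]")
    return 100.0 * n_established / n_samples
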
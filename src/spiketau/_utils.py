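"""Shared helpers: seeded RNG streams and window arithmetic."""

from __future__ import annotations

import numpy as np


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child generator keyed by integers.

    Streams keyed by e.g. (neuron, condition) are independent of how many
    other streams exist, so enlarging a simulation never perturbs draws
    already attributed to existing keys.
    """
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key)))


def check_window(window: tuple[float, float], bin_width: float | None = None) -> tuple[float, float]:
    lo, hi = float(window[0]), float(window[1])
    if not hi > lo:
        raise ValueError(f"window must satisfy start < end, got {window}")
    if bin_width is not None:
        n = (hi - lo) / bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"window length {hi - lo} ms is not a multiple of bin_width {bin_width} ms"
            )
    return lo, hi


def rate_in_window(spike_times: np.ndarray, window: tuple[float, float]) -> float:
    """Firing rate (spikes/s) of one trial in a half-open window given in ms."""
    lo, hi = window
    n = int(np.count_nonzero((spike_times >= lo) & (spike_times < hi)))
    return 1000.0 * n / (hi - lo)
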
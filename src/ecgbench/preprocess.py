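"""Signal preparation: resampling to the network frequency and forcing a
uniform input length.

Each architecture is tied to an input sampling frequency, so segments cut at
the dataset's native frequency are band-limited resampled (Fourier method)
to the network frequency, then cropped or zero-padded to the exact input
length.  No filtering, baseline-wander removal or amplitude normalization is
applied: the networks consume near-raw signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal


@dataclass(frozen=True)
class PreparedInput:
    samples: np.ndarray  # exactly target_len entries, at network fs
    fs: float
    record_id: str
    start: int  # start index at the original fs


def resample(samples: np.ndarray, from_fs: float, to_fs: float) -> np.ndarray:
    """Band-limited (Fourier) resampling.

    Output length is ``round(len * to_fs / from_fs)``, preserving total
    duration to within one sample period.
    """
    if from_fs <= 0 or to_fs <= 0:
        raise ValueError("sampling frequencies must be > 0")
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("cannot resample an empty signal")
    if from_fs == to_fs:
        return x.copy()
    n_out = int(round(x.size * to_fs / from_fs))
    return scipy.signal.resample(x, n_out)


def fit_length(samples: np.ndarray, target_len: int) -> np.ndarray:
    """Force the exact target length: crop the head-aligned signal if longer,
    append zeros at the tail if shorter.  Idempotent."""
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    x = np.asarray(samples, dtype=float)
    if x.size >= target_len:
        return x[:target_len].copy()
    return np.concatenate([x, np.zeros(target_len - x.size)])


def prepare(
    samples: np.ndarray,
    from_fs: float,
    to_fs: float,
    target_len: int,
    record_id: str = "",
    start: int = 0,
) -> PreparedInput:
    """Resample then fit to length; the standard two-step preparation."""
    y = fit_length(resample(samples, from_fs, to_fs), target_len)
    return PreparedInput(samples=y, fs=to_fs, record_id=record_id, start=start)
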
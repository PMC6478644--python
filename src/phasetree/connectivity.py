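"""Phase lag index (PLI) estimation between ROI phase series.

The PLI quantifies the asymmetry of the distribution of instantaneous phase
differences between two signals:

    PLI(i, j) = | < sign( sin( phi_i(t) - phi_j(t) ) ) >_t |

It ranges from 0 (symmetric phase-difference distribution — including the
zero-lag case produced by linear signal mixing) to 1 (a consistent nonzero
phase lag, i.e. perfect lagged synchronization).  The sign of the sine of the
phase difference is used rather than the sign of the wrapped difference
itself; the two are identical, but the sine form is immune to branch
artifacts at +/-pi.  Samples with exactly zero phase difference contribute
sign 0, so the PLI of a signal with itself is exactly 0.

The matrix form computes every unordered ROI pair of one phase epoch,
yielding a symmetric zero-diagonal adjacency matrix with entries in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import PhaseEpoch

__all__ = ["AdjacencyMatrix", "pli", "pli_matrix"]


@dataclass
class AdjacencyMatrix:
    """Symmetric PLI matrix for one subject x epoch x band."""

    subject_id: str
    epoch_index: int
    band: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("adjacency matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("PLI values must lie in [0, 1]")


def pli(phase_i: np.ndarray, phase_j: np.ndarray) -> float:
    """PLI between two instantaneous-phase series (radians).

    Symmetric in its arguments; returns a value in [0, 1].
    """
    phase_i = np.asarray(phase_i, dtype=float)
    phase_j = np.asarray(phase_j, dtype=float)
    if phase_i.shape != phase_j.shape or phase_i.ndim != 1:
        raise ValueError("phase series must be 1-D and of equal length")
    if phase_i.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.abs(np.mean(np.sign(np.sin(phase_i - phase_j)))))


def pli_matrix(phase_epoch: PhaseEpoch | np.ndarray) -> np.ndarray:
    """PLI between all unordered ROI pairs of one phase epoch.

    Accepts a :class:`~phasetree.spectral.PhaseEpoch` or a raw
    ``(n_rois, n_samples)`` phase array; returns the ``(n_rois, n_rois)``
    symmetric zero-diagonal matrix.
    """
    phases = phase_epoch.data if isinstance(phase_epoch, PhaseEpoch) else phase_epoch
    phases = np.asarray(phases, dtype=float)
    if phases.ndim != 2 or phases.shape[0] < 3:
        raise ValueError("need a 2-D phase array with at least 3 ROIs")
    n = phases.shape[0]
    out = np.zeros((n, n))
    # row-chunked to keep the (n, T) temporaries small
    for i in range(n - 1):
        d = np.sin(phases[i + 1 :] - phases[i])
        out[i, i + 1 :] = np.abs(np.mean(np.sign(d), axis=-1))
    out += out.T
    return out
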
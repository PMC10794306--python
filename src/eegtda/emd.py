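"""Empirical mode decomposition and amplitude-threshold artifact cleaning.

EMD splits a signal into intrinsic mode functions (IMFs) — data-driven
oscillatory components, highest frequency first — by iteratively
subtracting the mean of cubic-spline envelopes through the local extrema
(sifting). The decomposition is exactly additive: the input equals the
sum of the IMFs plus the final residual trend.

Artifact cleaning exploits that additivity: ocular and movement
transients are large and slow, so they concentrate in late IMFs / the
residual; dropping every component whose peak amplitude exceeds a
threshold (100 uV by default) and summing the survivors removes the
artifact while preserving sub-threshold brain activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import peak_prominences

__all__ = ["IMFDecomposition", "emd_decompose", "emd_clean"]


@dataclass
class IMFDecomposition:
    """Ordered IMFs (highest frequency first) and the residual trend."""

    imfs: list
    residual: np.ndarray

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


def _local_extrema(x: np.ndarray):
    """Indices of strict local maxima and minima (plateau midpoints)."""
    d = np.diff(x)
    # collapse flat segments so plateaus yield a single extremum
    nz = np.nonzero(d)[0]
    if nz.size < 2:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    sign = np.sign(d[nz])
    flips = np.nonzero(np.diff(sign))[0]
    idx = nz[flips] + 1
    maxima = idx[sign[flips] > 0]
    minima = idx[sign[flips] < 0]
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema, mirror-extended at the ends."""
    n = len(x)
    k = min(2, len(idx))
    left = -idx[:k][::-1]
    right = 2 * (n - 1) - idx[-k:][::-1]
    xi = np.concatenate([left, idx, right])
    yi = np.concatenate([x[idx[:k][::-1]], x[idx], x[idx[-k:][::-1]]])
    keep = np.concatenate([[True], np.diff(xi) > 0])
    xi, yi = xi[keep], yi[keep]
    if len(xi) < 2:
        return np.full(n, yi[0] if len(yi) else 0.0)
    bc = "not-a-knot" if len(xi) >= 4 else "natural"
    return CubicSpline(xi, yi, bc_type=bc)(np.arange(n))


def _has_significant_oscillation(res: np.ndarray,
                                 rel_tol: float = 0.02) -> bool:
    """Whether a component still carries modes worth sifting out.

    Extrema whose prominence is below ``rel_tol`` of the component's
    range are interpolation noise riding a trend, not oscillations;
    sifting them out only amplifies spline overshoot. Requires at least
    two significant maxima and two significant minima (the minimum to
    support an envelope pair).
    """
    maxima, minima = _local_extrema(res)
    if len(maxima) < 2 or len(minima) < 2:
        return False
    span = float(np.ptp(res))
    if span == 0:
        return False
    sig_max = int(np.sum(peak_prominences(res, maxima)[0] >= rel_tol * span))
    sig_min = int(np.sum(peak_prominences(-res, minima)[0] >= rel_tol * span))
    return sig_max >= 2 and sig_min >= 2


def _is_imf(h: np.ndarray) -> bool:
    """Extrema and zero-crossing counts differ by at most one."""
    maxima, minima = _local_extrema(h)
    n_ext = len(maxima) + len(minima)
    n_zc = int(np.sum(np.diff(np.sign(h)[np.sign(h) != 0]) != 0))
    return abs(n_ext - n_zc) <= 1


def emd_decompose(signal: np.ndarray, max_imfs: int = 10,
                  max_siftings: int = 10, sd_tol: float = 0.05
                  ) -> IMFDecomposition:
    """Sift a 1-D signal into IMFs plus a residual.

    Stopping rules: sifting of one mode ends once the Cauchy criterion
    ``sum((h_prev - h)^2) / sum(h_prev^2) < sd_tol`` is met *and* the
    candidate satisfies the IMF extrema/zero-crossing condition (the
    energy criterion alone can quit while a large transient still leaks
    into the mode), or after ``max_siftings`` iterations. The
    decomposition stops when the residual carries no significant
    oscillation (see ``_has_significant_oscillation``) or ``max_imfs``
    is reached. A constant or monotone input yields zero IMFs and
    residual = input.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if len(x) < 8:
        raise ValueError("signal too short for EMD (need >= 8 samples)")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")

    imfs: list[np.ndarray] = []
    residual = x.copy()
    for _ in range(max_imfs):
        if not _has_significant_oscillation(residual):
            break
        h = residual.copy()
        for _ in range(max_siftings):
            maxima, minima = _local_extrema(h)
            if len(maxima) < 2 or len(minima) < 2:
                break
            mean_env = 0.5 * (_envelope(h, maxima) + _envelope(h, minima))
            h_new = h - mean_env
            denom = float(np.sum(h * h))
            sd = float(np.sum(mean_env * mean_env)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sd_tol and _is_imf(h):
                break
        imfs.append(h)
        residual = residual - h
    return IMFDecomposition(imfs=imfs, residual=residual)


def emd_clean(epoch: np.ndarray, threshold_uv: float = 100.0,
              **emd_kwargs) -> np.ndarray:
    """Remove super-threshold IMFs per channel and resynthesise the epoch.

    Each channel is decomposed independently; every IMF — and the
    residual, subjected to the same rule — whose maximum absolute
    amplitude strictly exceeds ``threshold_uv`` is discarded, and the
    survivors are summed. Components exactly at the threshold are kept.
    Output shape equals input shape.
    """
    epoch = np.asarray(epoch, dtype=float)
    one_d = epoch.ndim == 1
    chans = epoch[None, :] if one_d else epoch
    out = np.zeros_like(chans)
    for c in range(chans.shape[0]):
        dec = emd_decompose(chans[c], **emd_kwargs)
        for comp in [*dec.imfs, dec.residual]:
            if np.max(np.abs(comp)) <= threshold_uv:
                out[c] += comp
    return out[0] if one_d else out
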
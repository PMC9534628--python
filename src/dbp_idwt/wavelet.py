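"""Two-level discrete wavelet compression of descriptor signals.

Each descriptor signal is split by a filter-bank DWT into approximation
(low-pass) and detail (high-pass) coefficients with dyadic
downsampling; the level-1 approximation is decomposed once more.  The
concatenation [cA2, cD2, cD1] is mapped deterministically to a fixed
512-length vector (truncate if longer, zero-pad at the tail if
shorter), which is what makes variable-length inputs comparable.

Periodization is the default boundary mode: coefficient counts halve
exactly and orthogonal wavelets conserve energy,
``||x||^2 == ||cA||^2 + ||cD||^2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from dbp_idwt.encoders import FeatureVector, ReducedProfile

DEFAULT_WAVELET = "haar"
DEFAULT_MODE = "periodization"
DEFAULT_OUT_LEN = 512

#: Wavelet families accepted by :func:`dwt_level`.
SUPPORTED_WAVELETS = tuple(
    name for name in pywt.wavelist(kind="discrete") if name.startswith(("haar", "db"))
)


@dataclass
class DwtResult:
    """Coefficients of a two-level decomposition."""

    approx_l1: np.ndarray
    detail_l1: np.ndarray
    approx_l2: np.ndarray
    detail_l2: np.ndarray
    wavelet_name: str
    level: int = 2


def _check_wavelet(wavelet_name: str) -> pywt.Wavelet:
    if wavelet_name not in SUPPORTED_WAVELETS:
        raise ValueError(
            f"unknown wavelet {wavelet_name!r}; supported: "
            + ", ".join(SUPPORTED_WAVELETS)
        )
    return pywt.Wavelet(wavelet_name)


def dwt_level(
    signal: np.ndarray, wavelet_name: str = DEFAULT_WAVELET, mode: str = DEFAULT_MODE
) -> tuple[np.ndarray, np.ndarray]:
    """One level of DWT: (approximation, detail) coefficient vectors."""
    wavelet = _check_wavelet(wavelet_name)
    signal = np.asarray(signal, dtype=float).ravel()
    if signal.size < wavelet.dec_len:
        raise ValueError(
            f"signal length {signal.size} shorter than the {wavelet_name} "
            f"filter length {wavelet.dec_len}"
        )
    approx, detail = pywt.dwt(signal, wavelet, mode=mode)
    return approx, detail


def dwt_decompose(
    signal: np.ndarray, wavelet_name: str = DEFAULT_WAVELET, mode: str = DEFAULT_MODE
) -> DwtResult:
    """Two-level decomposition; the second pass consumes the level-1
    approximation."""
    approx_l1, detail_l1 = dwt_level(signal, wavelet_name, mode)
    approx_l2, detail_l2 = dwt_level(approx_l1, wavelet_name, mode)
    return DwtResult(approx_l1, detail_l1, approx_l2, detail_l2, wavelet_name)


def _as_signal(feature: FeatureVector | ReducedProfile | np.ndarray) -> tuple[np.ndarray, str, str]:
    if isinstance(feature, FeatureVector):
        return feature.values, feature.descriptor_name, feature.source_id
    if isinstance(feature, ReducedProfile):
        # length-dependent signal, fixed-length output: the point of the
        # compression step for the reduced profile
        return feature.values.ravel(), "R-PSSM", feature.source_id
    arr = np.asarray(feature, dtype=float)
    return arr.ravel(), "signal", ""


def dwt_compress(
    feature: FeatureVector | ReducedProfile | np.ndarray,
    wavelet_name: str = DEFAULT_WAVELET,
    out_len: int = DEFAULT_OUT_LEN,
    mode: str = DEFAULT_MODE,
) -> FeatureVector:
    """Compress a descriptor to a fixed ``out_len`` vector.

    Applies :func:`dwt_level` twice, concatenates [cA2, cD2, cD1] and
    truncates / zero-pads at the tail to exactly ``out_len`` entries.
    Accepts a pre-DWT :class:`FeatureVector`, a :class:`ReducedProfile`
    (flattened row-major), or a raw array.
    """
    signal, name, source_id = _as_signal(feature)
    res = dwt_decompose(signal, wavelet_name, mode)
    coeffs = np.concatenate([res.approx_l2, res.detail_l2, res.detail_l1])
    if coeffs.size >= out_len:
        out = coeffs[:out_len]
    else:
        out = np.zeros(out_len)
        out[: coeffs.size] = coeffs
    out_name = name if name.endswith("-DWT") else f"{name}-DWT"
    return FeatureVector(out_name, out, source_id)
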
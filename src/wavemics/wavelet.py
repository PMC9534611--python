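"""Multidimensional discrete-wavelet feature construction.

Each patient's selected-feature row is laid out as a 4 x ceil(m/4) matrix
(one row per MRI sequence, zero-padded on the right when 4 does not divide
m), pushed through a single-level separable 2D DWT under each of 31 named
filter banks, and summarized into a 36-criterion profile:

* 7 matrix criteria (max, min, mean, median, sd, Shannon entropy of the
  normalized coefficient-energy distribution, signal energy) for each of
  cA, cH, cV, cD  -> 28 values;
* OLS slope and slope standard error of each detail matrix regressed on the
  approximation matrix -> 6 values;
* energy and waveform length of the whole (unpadded) input signal -> 2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pywt
from scipy import stats

#: The 31 filter banks: biorthogonal (11), Daubechies db2-db9 (8),
#: symlets sym2-sym8 (7), coiflets coif1-coif5 (5).
FILTER_BANKS = (
    "bior1.3", "bior1.5", "bior2.2", "bior2.4", "bior2.6", "bior3.1",
    "bior3.3", "bior3.5", "bior3.7", "bior4.4", "bior5.5",
    "db2", "db3", "db4", "db5", "db6", "db7", "db8", "db9",
    "sym2", "sym3", "sym4", "sym5", "sym6", "sym7", "sym8",
    "coif1", "coif2", "coif3", "coif4", "coif5",
)

_MATRIX_TAGS = ("cA", "cH", "cV", "cD")
_CRITERIA = ("max", "min", "mean", "median", "std", "entropy", "energy")

#: canonical names/order of the 36 profile entries
PROFILE_NAMES = tuple(
    [f"{m}_{c}" for m in _MATRIX_TAGS for c in _CRITERIA]
    + [f"{m}_{what}" for m in ("cH", "cV", "cD") for what in ("slope", "stderr")]
    + ["signal_energy", "signal_waveform_length"]
)

N_SEQUENCE_ROWS = 4


def reshape_signal(row: np.ndarray) -> tuple[np.ndarray, int]:
    """Lay out m selected values as a 4 x ceil(m/4) matrix.

    Values fill row-major (sequence-major assembly order maps one MRI
    sequence per matrix row); missing cells are zero-padded on the right of
    the last row. Returns (matrix, number of padded cells).
    """
    v = np.asarray(row, dtype=np.float64).ravel()
    m = v.size
    if m < N_SEQUENCE_ROWS:
        raise ValueError(f"need at least {N_SEQUENCE_ROWS} values, got {m}")
    ncol = -(-m // N_SEQUENCE_ROWS)
    n_pad = N_SEQUENCE_ROWS * ncol - m
    padded = np.concatenate([v, np.zeros(n_pad)])
    return padded.reshape(N_SEQUENCE_ROWS, ncol), n_pad


def dwt2_single_level(
    matrix: np.ndarray, bank: str, mode: str = "symmetric"
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Single-level separable 2D DWT -> (cA, cH, cV, cD)."""
    if bank not in FILTER_BANKS:
        raise ValueError(f"unknown filter bank {bank!r}; valid: {', '.join(FILTER_BANKS)}")
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or min(matrix.shape) < 2:
        raise ValueError("input matrix must be at least 2x2")
    cA, (cH, cV, cD) = pywt.dwt2(matrix, bank, mode=mode)
    return cA, cH, cV, cD


def matrix_criteria(M: np.ndarray) -> dict[str, float]:
    """The 7 per-matrix criteria.

    Shannon entropy is taken over p_i = m_i^2 / sum(m^2) (coefficients are
    signed, so the energy distribution supplies the probability mass), in
    bits, with 0*log0 = 0; an all-zero matrix has entropy 0.
    """
    x = np.asarray(M, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty matrix")
    energy = float((x**2).sum())
    if energy > 0:
        p = x**2 / energy
        nz = p[p > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
    else:
        entropy = 0.0
    return {
        "max": float(x.max()),
        "min": float(x.min()),
        "mean": float(x.mean()),
        "median": float(np.median(x)),
        "std": float(x.std()),
        "entropy": entropy,
        "energy": energy,
    }


def pair_regression(cA: np.ndarray, detail: np.ndarray) -> tuple[float, float]:
    """OLS fit (with intercept) of flattened detail values on flattened cA
    values; returns (slope, standard error of the slope).

    A zero-variance cA makes the fit degenerate: (0.0, 0.0) by convention.
    """
    a = np.asarray(cA, dtype=np.float64).ravel()
    d = np.asarray(detail, dtype=np.float64).ravel()
    if a.shape != d.shape:
        raise ValueError("cA and detail must have equal shapes")
    if a.size < 3:
        raise ValueError("need at least 3 cells for the regression")
    if np.ptp(a) == 0:
        return 0.0, 0.0
    res = stats.linregress(a, d)
    stderr = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return float(res.slope), stderr


def whole_signal_criteria(row: np.ndarray) -> tuple[float, float]:
    """(energy, waveform length) of the original 1D signal.

    Waveform length is the summed absolute first difference
    sum |x_{i+1} - x_i| — the standard signal-criterion reading of
    'wavelength'.
    """
    v = np.asarray(row, dtype=np.float64).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values")
    return float((v**2).sum()), float(np.abs(np.diff(v)).sum())


def build_profile(row: np.ndarray, bank: str) -> pd.Series:
    """The 36-criterion profile of one sample under one filter bank."""
    matrix, _ = reshape_signal(row)
    cA, cH, cV, cD = dwt2_single_level(matrix, bank)
    values: dict[str, float] = {}
    for tag, M in zip(_MATRIX_TAGS, (cA, cH, cV, cD)):
        crit = matrix_criteria(M)
        values.update({f"{tag}_{c}": crit[c] for c in _CRITERIA})
    for tag, M in zip(("cH", "cV", "cD"), (cH, cV, cD)):
        slope, stderr = pair_regression(cA, M)
        values[f"{tag}_slope"] = slope
        values[f"{tag}_stderr"] = stderr
    energy, wl = whole_signal_criteria(row)
    values["signal_energy"] = energy
    values["signal_waveform_length"] = wl
    out = pd.Series(values)[list(PROFILE_NAMES)]
    assert len(out) == 36
    return out


def build_all_profiles(
    table: pd.DataFrame, banks: tuple[str, ...] = FILTER_BANKS
) -> dict[str, pd.DataFrame]:
    """One 36-column profile table per filter bank, rows aligned to the
    input table's rows (patients)."""
    feature_cols = [c for c in table.columns if c != "label"]
    profiles: dict[str, pd.DataFrame] = {}
    for bank in banks:
        try:
            rows = [
                build_profile(table.loc[idx, feature_cols].to_numpy(), bank)
                for idx in table.index
            ]
        except Exception as exc:  # noqa: BLE001 - reraise with the bank named
            raise RuntimeError(f"profile construction failed for bank {bank!r}: {exc}") from exc
        prof = pd.DataFrame(rows, index=table.index)
        if "label" in table.columns:
            prof["label"] = table["label"]
        profiles[bank] = prof
    return profiles
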
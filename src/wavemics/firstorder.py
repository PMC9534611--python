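"""First-order intensity statistics of an ROI.

Order statistics and moments are computed on the raw in-mask intensities;
Entropy and Uniformity on the fixed-bin-width discretized histogram, the
convention of mainstream radiomics extractors.
"""

from __future__ import annotations

import numpy as np

from .datatypes import DiscretizedROI

FIRSTORDER_FEATURE_NAMES = (
    "10Percentile",
    "90Percentile",
    "Energy",
    "Entropy",
    "InterquartileRange",
    "Kurtosis",
    "Maximum",
    "MeanAbsoluteDeviation",
    "Mean",
    "Median",
    "Minimum",
    "Range",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "TotalEnergy",
    "Uniformity",
    "Variance",
)


def firstorder_features(
    droi: DiscretizedROI,
    raw_intensities: np.ndarray,
    voxel_volume: float = 1.0,
) -> dict[str, float]:
    """The 18 first-order statistics.

    Parameters
    ----------
    droi : discretized ROI supplying the histogram for Entropy/Uniformity.
    raw_intensities : flat array of the raw in-mask intensities.
    voxel_volume : single-voxel volume in mm^3 (for TotalEnergy).

    Skewness and kurtosis of a constant ROI are defined as 0 (the central
    second moment vanishes); kurtosis is the raw (non-excess) form m4/m2^2.
    """
    x = np.asarray(raw_intensities, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    n = x.size

    mean = x.mean()
    cent = x - mean
    m2 = np.mean(cent**2)
    m3 = np.mean(cent**3)
    m4 = np.mean(cent**4)
    skew = float(m3 / m2**1.5) if m2 > 0 else 0.0
    kurt = float(m4 / m2**2) if m2 > 0 else 0.0

    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    levels = droi.roi_levels
    counts = np.bincount(levels, minlength=droi.n_levels + 1)[1:]
    p = counts / counts.sum()
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    uniformity = float((p**2).sum())

    energy = float((x**2).sum())
    return {
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Energy": energy,
        "Entropy": entropy,
        "InterquartileRange": float(p75 - p25),
        "Kurtosis": kurt,
        "Maximum": float(x.max()),
        "MeanAbsoluteDeviation": float(np.abs(cent).mean()),
        "Mean": float(mean),
        "Median": float(np.median(x)),
        "Minimum": float(x.min()),
        "Range": float(x.max() - x.min()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "TotalEnergy": float(voxel_volume * energy),
        "Uniformity": uniformity,
        "Variance": float(m2),
    }
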
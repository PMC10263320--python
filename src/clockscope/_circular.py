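"""Circular (angular) helper statistics shared across modules.

All angles are radians. Phases live on [0, 2*pi); signed differences on
(-pi, pi]. The Fisher-Lee T-linear association coefficient is used wherever
two sets of angles must be compared (e.g. inferred vs. true sample phases):
it is invariant to rotation of either variable and changes sign under
reflection, which matches the identifiability of a learned circular
coordinate (known only up to rotation and direction).
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap(theta: np.ndarray | float) -> np.ndarray | float:
    """Map angles onto [0, 2*pi)."""
    return np.mod(theta, TWO_PI)


def circ_diff(a, b):
    """Signed circular difference a - b in (-pi, pi]."""
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + np.pi, TWO_PI) - np.pi
    # map -pi to +pi so the interval is half-open on the left
    return np.where(np.isclose(d, -np.pi), np.pi, d) if np.ndim(d) else (np.pi if np.isclose(d, -np.pi) else float(d))


def circ_dist(a, b):
    """Absolute circular distance in [0, pi]."""
    return np.abs(circ_diff(a, b))


def circ_mean(theta: np.ndarray) -> float:
    """Circular mean direction of a sample of angles."""
    theta = np.asarray(theta, dtype=float)
    return float(np.mod(np.arctan2(np.sin(theta).sum(), np.cos(theta).sum()), TWO_PI))


def fisher_lee_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Fisher-Lee T-linear circular-circular association coefficient.

    r = sum_{i<j} sin(a_i - a_j) sin(b_i - b_j)
        / sqrt( sum_{i<j} sin^2(a_i-a_j) * sum_{i<j} sin^2(b_i-b_j) )

    Returns 0.0 if either variable is angularly degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("angle vectors must have equal length")
    da = np.sin(np.subtract.outer(a, a))
    db = np.sin(np.subtract.outer(b, b))
    num = float(np.sum(da * db))
    den = float(np.sqrt(np.sum(da * da) * np.sum(db * db)))
    if den == 0.0:
        return 0.0
    return num / den


def align_to_reference(est: np.ndarray, ref: np.ndarray):
    """Best rotation/reflection alignment of estimated angles onto reference.

    Tries both orientations (est and -est); for each, the optimal global
    rotation is the circular mean of the residuals. Returns a dict with the
    aligned angles, the (signed-optimal) Fisher-Lee correlation, and the
    median absolute circular error of the better orientation.
    """
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("length mismatch between estimated and reference angles")
    best = None
    for sign in (1.0, -1.0):
        cand = wrap(sign * est)
        rot = circ_mean(circ_diff(ref, cand))
        aligned = wrap(cand + rot)
        err = np.abs(circ_diff(aligned, ref))
        med = float(np.median(err))
        if best is None or med < best["median_abs_error"]:
            best = {
                "aligned": aligned,
                "median_abs_error": med,
                "sign": sign,
                "rotation": rot,
            }
    best["correlation"] = abs(fisher_lee_correlation(est, ref))
    return best
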
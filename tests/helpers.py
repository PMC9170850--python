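"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as explicit per-voxel / per-cell summation so it
shares no code path with the package's vectorized geometry or the ANOVA
routines it verifies.
"""

import numpy as np


def brute_sphere_mask(vol, center, radius):
    """Exhaustive center-in-sphere loop (strict interior)."""
    out = np.zeros(vol.shape, dtype=bool)
    for i in range(vol.shape[0]):
        for j in range(vol.shape[1]):
            for k in range(vol.shape[2]):
                p = [vol.origin[a] + (i, j, k)[a] * vol.spacing[a] for a in range(3)]
                d2 = sum((p[a] - center[a]) ** 2 for a in range(3))
                if d2 < radius**2:
                    out[i, j, k] = True
    return out


def brute_tube_mask(vol, points, radii):
    """Exhaustive capless-sweep loop: perpendicular band per segment, min distance."""
    out = np.zeros(vol.shape, dtype=bool)
    points = np.asarray(points, dtype=float)
    radii = np.asarray(radii, dtype=float)
    for i in range(vol.shape[0]):
        for j in range(vol.shape[1]):
            for k in range(vol.shape[2]):
                p = np.array(
                    [vol.origin[a] + (i, j, k)[a] * vol.spacing[a] for a in range(3)]
                )
                best_d2, best_r = np.inf, 0.0
                for s in range(len(points) - 1):
                    d = points[s + 1] - points[s]
                    t = float(np.dot(p - points[s], d) / np.dot(d, d))
                    if t < 0.0 or t > 1.0:
                        continue
                    q = points[s] + t * d
                    d2 = float(np.dot(p - q, p - q))
                    if d2 < best_d2:
                        best_d2 = d2
                        best_r = radii[s] + t * (radii[s + 1] - radii[s])
                if best_d2 <= best_r**2:
                    out[i, j, k] = True
    return out


def anova_icc_consistency(matrix):
    """ICC(C,1) by explicit two-way ANOVA summation: (MSR - MSE)/(MSR + (k-1) MSE)."""
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    grand = 0.0
    for i in range(n):
        for j in range(k):
            grand += m[i, j]
    grand /= n * k
    row_means = [sum(m[i, j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(m[i, j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_err = 0.0
    for i in range(n):
        for j in range(k):
            ss_err += (m[i, j] - row_means[i] - col_means[j] + grand) ** 2
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse)


def summation_bland_altman(a, b):
    """Bias and 1.96-sd limits by explicit summation (n-1 sd)."""
    d = [bb - aa for aa, bb in zip(a, b)]
    n = len(d)
    bias = sum(d) / n
    sd = (sum((x - bias) ** 2 for x in d) / (n - 1)) ** 0.5
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def summation_cr(a, b):
    d = [bb - aa for aa, bb in zip(a, b)]
    n = len(d)
    mean = sum(d) / n
    sd = (sum((x - mean) ** 2 for x in d) / (n - 1)) ** 0.5
    return 1.96 * sd
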
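"""Independent brute-force oracles used across the test suite.

Everything here is written as plainly as possible (explicit Python loops,
closed-form normal equations, central finite differences) and must stay
independent of the implementation paths it checks.
"""

import math

import numpy as np

#: skimage angle (radians) matching each package orientation for d=1.
SKIMAGE_ANGLES = {0: 0.0, 45: -np.pi / 4, 90: -np.pi / 2, 135: -3 * np.pi / 4}


def brute_energy(P):
    total = 0.0
    for i in range(P.shape[0]):
        for j in range(P.shape[1]):
            total += P[i, j] ** 2
    return total


def brute_entropy(P, base=2.0):
    total = 0.0
    for i in range(P.shape[0]):
        for j in range(P.shape[1]):
            if P[i, j] > 0:
                total -= P[i, j] * math.log(P[i, j], base)
    return total


def brute_contrast(P):
    total = 0.0
    for i in range(P.shape[0]):
        for j in range(P.shape[1]):
            total += (i - j) ** 2 * P[i, j]
    return total


def brute_homogeneity(P):
    total = 0.0
    for i in range(P.shape[0]):
        for j in range(P.shape[1]):
            total += P[i, j] / (1.0 + (i - j) ** 2)
    return total


def brute_correlation(P):
    ng = P.shape[0]
    px = [sum(P[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(P[i, j] for i in range(ng)) for j in range(ng)]
    mu_x = sum(i * px[i] for i in range(ng))
    mu_y = sum(j * py[j] for j in range(ng))
    sx = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(ng)))
    sy = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(ng)))
    if sx * sy == 0:
        return 1.0
    s = sum(i * j * P[i, j] for i in range(ng) for j in range(ng))
    return (s - mu_x * mu_y) / (sx * sy)


def brute_glcm(levels, ng, offset, symmetric=False):
    """Count co-occurring pairs with explicit loops; offset is (dr, dc)."""
    dr, dc = offset
    counts = np.zeros((ng, ng))
    nrow, ncol = levels.shape
    for r in range(nrow):
        for c in range(ncol):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nrow and 0 <= c2 < ncol:
                counts[levels[r, c], levels[r2, c2]] += 1
                if symmetric:
                    counts[levels[r2, c2], levels[r, c]] += 1
    return counts / counts.sum()


def ols_normal_equations(x, y):
    """Closed-form simple linear regression: slope and intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def finite_difference_gradients(net, Xs, ts, eps=1e-5):
    """Central finite differences of the scaled-space MSE loss wrt every
    weight and bias, using only the network's forward pass."""
    from ct2bmd.neuralnet import mse as _mse

    def loss():
        return _mse(net.forward_scaled(Xs), ts)

    grads = {}
    for name in ("W1", "b1", "W2"):
        arr = getattr(net, name)
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + eps
            hi = loss()
            arr[idx] = orig - eps
            lo = loss()
            arr[idx] = orig
            g[idx] = (hi - lo) / (2 * eps)
        grads[name] = g
    orig = net.b2
    net.b2 = orig + eps
    hi = loss()
    net.b2 = orig - eps
    lo = loss()
    net.b2 = orig
    grads["b2"] = (hi - lo) / (2 * eps)
    return grads
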
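"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive — plain loops and textbook formulas —
and shares no code with the implementation under test.
"""

import math

import numpy as np
from scipy.optimize import minimize


def naive_hog(patch, cell=(4, 8), block=(2, 2), bins=10, stride=1, eps=1e-5):
    """Double-loop HOG: grayscale, [-1,0,1] gradients with replicated
    borders, bilinear orientation voting, L2 block normalization."""
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim == 3:
        gray = (
            0.299 * patch[..., 0] + 0.587 * patch[..., 1] + 0.114 * patch[..., 2]
        )
    else:
        gray = patch
    h, w = gray.shape
    cw, ch = cell
    ncx, ncy = w // cw, h // ch
    hist = np.zeros((ncy, ncx, bins))
    bin_width = 180.0 / bins
    for y in range(h):
        for x in range(w):
            xl = gray[y, max(x - 1, 0)]
            xr = gray[y, min(x + 1, w - 1)]
            yu = gray[max(y - 1, 0), x]
            yd = gray[min(y + 1, h - 1), x]
            gx = xr - xl
            gy = yd - yu
            mag = math.hypot(gx, gy)
            ang = math.degrees(math.atan2(gy, gx)) % 180.0
            pos = ang / bin_width - 0.5
            b0 = math.floor(pos)
            frac = pos - b0
            lo = b0 % bins
            hi = (lo + 1) % bins
            cy_, cx_ = y // ch, x // cw
            hist[cy_, cx_, lo] += mag * (1.0 - frac)
            hist[cy_, cx_, hi] += mag * frac
    bw, bh = block
    out = []
    for by in range(0, ncy - bh + 1, stride):
        for bx in range(0, ncx - bw + 1, stride):
            vec = []
            for dy in range(bh):
                for dx in range(bw):
                    vec.extend(hist[by + dy, bx + dx])
            vec = np.asarray(vec)
            out.append(vec / math.sqrt(float(vec @ vec) + eps**2))
    return np.concatenate(out)


def nb_posterior_mask(means, variances, priors, image):
    """Per-pixel argmax of Gaussian NB log posteriors over (R-G, R-B, f3)."""
    h, w = image.shape[:2]
    mask = np.zeros((h, w), dtype=bool)
    for y in range(h):
        for x in range(w):
            r, g, b = (float(v) for v in image[y, x])
            total = r + g + b
            feats = [r - g, r - b, (r / total) if total > 0 else 0.0]
            scores = []
            for cls in range(2):
                s = math.log(priors[cls])
                for j in range(3):
                    var = variances[cls][j]
                    s -= 0.5 * (
                        (feats[j] - means[cls][j]) ** 2 / var
                        + math.log(2 * math.pi * var)
                    )
                scores.append(s)
            mask[y, x] = scores[1] >= scores[0]
    return mask


def svm_primal_qp(X, y, C=1.0):
    """Brute-force soft-margin SVM: minimize the primal QP with explicit
    slack variables under linear constraints (SLSQP). Returns the optimal
    objective value."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, d = X.shape

    def unpack(z):
        return z[:d], z[d], z[d + 1:]

    def objective(z):
        w, b, xi = unpack(z)
        return 0.5 * float(w @ w) + C * float(xi.sum())

    constraints = [
        {
            "type": "ineq",
            "fun": (lambda z, i=i: (
                y[i] * (X[i] @ z[:d] + z[d]) - 1.0 + z[d + 1 + i]
            )),
        }
        for i in range(n)
    ]
    bounds = [(None, None)] * (d + 1) + [(0.0, None)] * n
    z0 = np.zeros(d + 1 + n)
    z0[d + 1:] = 1.0
    res = minimize(
        objective, z0, method="SLSQP", bounds=bounds, constraints=constraints,
        options={"maxiter": 1000, "ftol": 1e-12},
    )
    assert res.success, res.message
    return res.fun


def auc_concordance(scores, labels):
    """Pairwise concordance AUC with half-credit for ties."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
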
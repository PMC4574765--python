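"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths (and libraries) the package uses
for the same quantities: the BH rule is a literal transcription of the
step-up definition, and the Welch test is the closed-form formula plus
the t survival function.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import t as t_dist


def bh_stepup(pvals: list[float]) -> list[float]:
    """Literal Benjamini–Hochberg step-up rule, O(n^2), input order preserved.

    adj(i) = min over j with p_(j) >= p_(i)... implemented as: sort
    ascending, scale p_(k) by n/k, take the running minimum from the
    largest rank down, cap at 1, unsort.
    """
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    scaled = [min(1.0, pvals[order[k]] * n / (k + 1)) for k in range(n)]
    for k in range(n - 2, -1, -1):
        scaled[k] = min(scaled[k], scaled[k + 1])
    out = [0.0] * n
    for k, idx in enumerate(order):
        out[idx] = scaled[k]
    return out


def welch_closed_form(x, y) -> tuple[float, float]:
    """Welch t statistic, Welch–Satterthwaite df, two-sided p from t.sf."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx = x.var(ddof=1) / nx
    vy = y.var(ddof=1) / ny
    t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (nx - 1) + vy**2 / (ny - 1))
    p = 2.0 * t_dist.sf(abs(t), df)
    return t, p
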
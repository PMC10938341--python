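"""Independent brute-force reference implementations used only by the tests.

Each function re-derives a quantity from first principles, deliberately
sharing no code with the package, so tests can compare the two routes.
"""

import numpy as np


def plane_section_length(vertices, faces, axis, coord, eps=1e-9):
    """Sum of per-triangle plane-intersection segment lengths (no chaining)."""
    d = vertices[:, axis] - coord
    d = np.where(np.abs(d) < eps, eps, d)
    total = 0.0
    n_segments = 0
    for tri in faces:
        pts = []
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            da, db = d[a], d[b]
            if (da > 0) != (db > 0):
                t = da / (da - db)
                pts.append(vertices[a] + t * (vertices[b] - vertices[a]))
        if len(pts) == 2:
            total += float(np.linalg.norm(pts[1] - pts[0]))
            n_segments += 1
    return total, n_segments


def euler_characteristic(faces):
    """V - E + F from an explicitly constructed unique edge set."""
    edge_set = set()
    vert_set = set()
    for a, b, c in faces:
        vert_set.update((int(a), int(b), int(c)))
        for u, v in ((a, b), (b, c), (c, a)):
            edge_set.add((min(int(u), int(v)), max(int(u), int(v))))
    return len(vert_set) - len(edge_set) + len(faces)


def icc_a1(data):
    """ICC(A,1) from elementwise two-way ANOVA sums of squares."""
    data = np.asarray(data, float)
    n, k = data.shape
    grand = data.mean()
    msr = sum((data[i].mean() - grand) ** 2 for i in range(n)) * k / (n - 1)
    msc = sum((data[:, j].mean() - grand) ** 2 for j in range(k)) * n / (k - 1)
    sse = 0.0
    for i in range(n):
        for j in range(k):
            sse += (data[i, j] - data[i].mean() - data[:, j].mean() + grand) ** 2
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def rank_average(x):
    """Average ranks with midranks for ties, by explicit scanning."""
    x = np.asarray(x, float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for idx in order[i : j + 1]:
            ranks[idx] = avg
        i = j + 1
    return ranks


def spearman_via_pearson(x, y):
    """Spearman rho as Pearson correlation of average ranks."""
    rx, ry = rank_average(x), rank_average(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def bh_stepup_flags(p, alpha):
    """Benjamini-Hochberg step-up rejections by direct threshold scan."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    k = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= i * alpha / m:
            k = i
    flags = np.zeros(m, bool)
    flags[order[:k]] = True
    return flags


def mad_plain(values):
    med = float(np.median(values))
    return float(np.median([abs(v - med) for v in values]))


def mad_filter_survivors(times, n_mads=5.0):
    """Deliberation-time outlier filter, re-derived: MAD rule with the
    zero-MAD fallback of removing times above n_mads x median."""
    med = float(np.median(times))
    mad = mad_plain(times)
    if mad > 0:
        return [t for t in times if abs(t - med) <= n_mads * mad]
    return [t for t in times if t <= n_mads * med]


def residual_partial_corr(y, x, covariates):
    """Partial correlation of y and x given covariates, via double residualization."""
    Z = np.column_stack([np.ones(len(y))] + [np.asarray(c, float) for c in covariates])
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    return float(np.corrcoef(ry, rx)[0, 1])
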
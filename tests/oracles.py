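"""Independent brute-force oracles: pure-Python recomputation of every
compactness metric from raw pixel lists, and textbook correlation formulas.
Deliberately avoids the package's numpy code paths."""

import math


def pixel_list(grid):
    return [(r, c) for r in range(grid.shape[0]) for c in range(grid.shape[1]) if grid[r, c]]


def bf_centroid(pixels):
    n = len(pixels)
    x = sum(c for _, c in pixels) / n
    y = sum(r for r, _ in pixels) / n
    return (x, y)


def bf_overlaps(pixel_lists):
    """Pairwise overlap counts via set intersection, unordered pairs i<j."""
    sets = [set(p) for p in pixel_lists]
    out = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            out.append(len(sets[i] & sets[j]))
    return out


def bf_oss_ossd(sizes):
    n = len(sizes)
    oss = sum(sizes)
    mean = oss / n
    var = sum((s - mean) ** 2 for s in sizes) / n
    return oss, math.sqrt(var)


def bf_quantile_type7(values, q):
    xs = sorted(values)
    h = q * (len(xs) - 1)
    lo = math.floor(h)
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def bf_metrics(pixel_lists):
    """All ten metrics plus Lbbox from per-bone pixel lists."""
    cents = [bf_centroid(p) for p in pixel_lists]
    n = len(cents)
    mux = sum(x for x, _ in cents) / n
    muy = sum(y for _, y in cents) / n
    radii = [math.hypot(x - mux, y - muy) for x, y in cents]
    rmsr = math.sqrt(sum(r * r for r in radii) / n)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                total += math.hypot(cents[i][0] - cents[j][0], cents[i][1] - cents[j][1])
    mpd = total / (n * (n - 1))
    r50 = bf_quantile_type7(radii, 0.5)
    r90 = bf_quantile_type7(radii, 0.9)
    xs = [x for x, _ in cents]
    ys = [y for _, y in cents]
    lbbox = math.hypot(max(xs) - min(xs), max(ys) - min(ys))
    oss, ossd = bf_oss_ossd(bf_overlaps(pixel_lists))
    return {
        "OSS": oss, "OSSD": ossd, "RMSR": rmsr, "MPD": mpd,
        "R50": r50, "R90": r90, "Lbbox": lbbox,
        "RMSRn": rmsr / lbbox, "MPDn": mpd / lbbox,
        "R50n": r50 / lbbox, "R90n": r90 / lbbox,
    }


def bf_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
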
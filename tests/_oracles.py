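"""Independent brute-force reference implementations used only by tests.

Each oracle mirrors a package operation through a different route
(direct formulas, sort-and-interpolate, set algebra, scipy's
agglomeration) so that agreement is evidence, not tautology.
"""

import math
from itertools import combinations

import numpy as np


def percentile_linear(values, fraction: float) -> float:
    """Sort-and-interpolate percentile (linear interpolation), by hand."""
    s = sorted(float(v) for v in values)
    n = len(s)
    if n == 0:
        raise ValueError("empty")
    if n == 1:
        return s[0]
    h = fraction * (n - 1)
    lo = int(math.floor(h))
    hi = min(lo + 1, n - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def trimmed_mean_by_sort(values) -> float:
    s = sorted(float(v) for v in values)
    if len(s) < 3:
        return sum(s) / len(s)
    return sum(s[1:-1]) / (len(s) - 2)


def pearson_by_formula(x, y) -> float:
    """Covariance over product of standard deviations, written out."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / n)
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / n)
    return cov / (sx * sy)


def overlap_by_sets(presence, in_samples, out_samples):
    """(pct in both groups, pct in all samples) via explicit set algebra."""
    detected = {o for o in presence.index if any(presence.loc[o, s] for s in presence.columns)}
    in_set = {o for o in detected if any(presence.loc[o, s] for s in in_samples)}
    out_set = {o for o in detected if any(presence.loc[o, s] for s in out_samples)}
    all_set = {o for o in detected if all(presence.loc[o, s] for s in presence.columns)}
    n = len(detected)
    return 100.0 * len(in_set & out_set) / n, 100.0 * len(all_set) / n


def heatmap_filter_exhaustive(result, fold_min, alpha):
    """Loop over every OTU and apply the two filters literally."""
    keep = []
    for otu, row in result.iterrows():
        p = row["p"]
        f = row["fold_change"]
        if not (np.isfinite(p) and np.isfinite(f)):
            continue
        sym = max(f, 1.0 / f)
        if p < alpha and sym >= fold_min:
            keep.append(otu)
    return set(keep)


def upgma_by_scipy(similarity_df):
    """Average-linkage merges via scipy, as (merged-leafset, height) pairs."""
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    labels = list(similarity_df.index)
    D = 100.0 - similarity_df.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    clusters = {i: frozenset([lab]) for i, lab in enumerate(labels)}
    merges = []
    for k, (i, j, h, _n) in enumerate(Z):
        merged = clusters[int(i)] | clusters[int(j)]
        clusters[len(labels) + k] = merged
        merges.append((merged, float(h)))
    return merges


def structure_p_montecarlo(scores, weights, in_mask, n_draws, rng):
    """Random-relabelling estimate of the PC-test p-value."""
    n = len(in_mask)
    n_in = int(in_mask.sum())

    def stat(mask):
        d = scores[mask].mean(axis=0) - scores[~mask].mean(axis=0)
        return float((weights * d**2).sum())

    t_obs = stat(in_mask)
    count = 0
    for _ in range(n_draws):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=n_in, replace=False)] = True
        if stat(mask) >= t_obs - 1e-12:
            count += 1
    return count / n_draws
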
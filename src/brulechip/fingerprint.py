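"""Gel-fingerprint comparison: Pearson similarity, UPGMA, permutation test.

Lane profiles are first normalised to unit total intensity (Pearson
correlation is itself invariant to affine rescaling of a lane, so this
only guards the numerics), then every pair of lanes gets a similarity of
100 * Pearson r.  Groups of lanes are compared with a permutation test
on the similarity matrix whose statistic is the *percent dissimilarity*

    d = mean within-group similarity - mean between-group similarity,

in percent points.  The null permutes group labels over lanes — by
default within each site stratum for pooled tests — and
p = (#{d_perm >= d_obs} + 1) / (n_perm + 1); when the design admits
fewer distinct labellings than requested the null is enumerated exactly
instead (p = fraction of labellings with d >= d_obs, observed included).

UPGMA clusters lanes by maximum average similarity; the dendrogram is
emitted as newick with node heights equal to the merge dissimilarity
(100 - similarity) and ties broken toward the lexicographically
smallest member label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, product
from math import comb
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import DEFAULT_GROUPS, FingerprintSet, FingerprintTestResult

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Similarity
# ---------------------------------------------------------------------------


def similarity_matrix(fingerprints: FingerprintSet, normalize: bool = True) -> pd.DataFrame:
    """Sample x sample matrix of 100 * Pearson r between lane profiles."""
    lanes = fingerprints.lanes
    vals = lanes.to_numpy(dtype=float).T  # lanes x grid
    sd = vals.std(axis=1)
    flat = [lanes.columns[i] for i in np.flatnonzero(sd == 0)]
    if flat:
        raise ValueError(f"zero-variance lane(s): {flat}")
    if normalize:
        vals = vals / vals.sum(axis=1, keepdims=True)
    r = np.corrcoef(vals)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(100.0 * r, index=lanes.columns, columns=lanes.columns)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


@dataclass
class UpgmaTree:
    """UPGMA dendrogram: newick string plus the merge trace for audits."""

    newick: str
    #: (members_a, members_b, height) per merge, members as sorted tuples
    merges: List[Tuple[Tuple[str, ...], Tuple[str, ...], float]]

    @property
    def root_height(self) -> float:
        return self.merges[-1][2] if self.merges else 0.0


def upgma(similarity: pd.DataFrame) -> UpgmaTree:
    """Average-linkage agglomeration on dissimilarity 100 - similarity.

    At each step the pair of clusters with the smallest average
    dissimilarity (largest average similarity) merges at a height equal
    to that dissimilarity; ties are resolved toward the pair whose
    combined member list is lexicographically smallest (logged).
    Heights are non-decreasing along every root path (ultrametric).
    """
    labels = list(similarity.index)
    D = 100.0 - similarity.to_numpy(dtype=float)
    clusters: Dict[int, Tuple[Tuple[str, ...], int, float, str]] = {
        i: ((lab,), 1, 0.0, lab) for i, lab in enumerate(labels)
    }
    dist: Dict[Tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(len(labels)) for j in range(i + 1, len(labels))
    }
    merges: List[Tuple[Tuple[str, ...], Tuple[str, ...], float]] = []
    next_id = len(labels)
    while len(clusters) > 1:
        # smallest average dissimilarity; ties -> lexicographically smallest members
        def sort_key(item):
            (i, j), d = item
            return (d, tuple(sorted(clusters[i][0] + clusters[j][0])))

        (i, j), h = min(dist.items(), key=sort_key)
        if min(clusters[j][0]) < min(clusters[i][0]):
            i, j = j, i  # stable child order: smallest member label first
        mi, ni, hi, nwk_i = clusters[i]
        mj, nj, hj, nwk_j = clusters[j]
        if any(d == h for key, d in dist.items() if key != (i, j)):
            logger.debug("UPGMA tie at height %.6g resolved toward %s", h, sorted(mi + mj))
        newick = f"({nwk_i}:{h - hi:.6g},{nwk_j}:{h - hj:.6g})"
        merges.append((tuple(sorted(mi)), tuple(sorted(mj)), h))
        new = next_id
        next_id += 1
        for k in list(clusters):
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(min(new, k), max(new, k))] = (ni * dik + nj * djk) / (ni + nj)
        for key in [key for key in dist if i in key or j in key]:
            del dist[key]
        del clusters[i], clusters[j]
        clusters[new] = (tuple(sorted(mi + mj)), ni + nj, h, newick)
    (_members, _n, _h, nwk) = next(iter(clusters.values()))
    return UpgmaTree(newick=nwk + ";", merges=merges)


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------


def _pair_sums(S: np.ndarray, labels: np.ndarray) -> Tuple[float, float, int, int]:
    """Off-diagonal within/between sums and pair counts for one labelling."""
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(len(labels), dtype=bool)
    sw = float(S[same & off].sum())
    sb = float(S[~same].sum())
    return sw, sb, int((same & off).sum()), int((~same).sum())


def _dissimilarity(S: np.ndarray, labels: np.ndarray) -> float:
    sw, sb, cw, cb = _pair_sums(S, labels)
    if cw == 0 or cb == 0:
        raise ValueError("need at least 2 lanes in each group")
    return sw / cw - sb / cb


def _count_labellings(labels: np.ndarray, strata: np.ndarray) -> int:
    """Distinct label vectors preserving per-stratum label counts."""
    total = 1
    for s in np.unique(strata):
        sub = labels[strata == s]
        n = len(sub)
        for _, c in zip(*np.unique(sub, return_counts=True)):
            total *= comb(n, c)
            n -= c
    return total


def _enumerate_two_group(labels: np.ndarray, strata: np.ndarray, first_label) -> "np.ndarray":
    """All distinct two-label vectors with the observed per-stratum counts."""
    strat_ids = np.unique(strata)
    per_stratum = []
    for s in strat_ids:
        idx = np.flatnonzero(strata == s)
        k = int((labels[idx] == first_label).sum())
        per_stratum.append([idx[list(c)] for c in combinations(range(len(idx)), k)])
    out = []
    for combo in product(*per_stratum):
        mask = np.zeros(len(labels), dtype=bool)
        for idx in combo:
            mask[idx] = True
        out.append(mask)
    return np.array(out)


def permutation_group_test(
    similarity: pd.DataFrame,
    labels: pd.Series,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    strata: Optional[pd.Series] = None,
    label: str = "",
    force_random: bool = False,
) -> FingerprintTestResult:
    """Permutation test of group separation on a similarity matrix.

    ``labels`` assigns each lane its group (two or more groups);
    ``strata`` restricts label shuffling to within-stratum (e.g. sites)
    for pooled tests.  With a fixed seed the p-value is reproducible;
    p >= 1/(n_perm + 1) always.  ``force_random`` skips the exact
    enumeration shortcut (used to cross-check exact p-values against
    Monte-Carlo estimates).
    """
    samples = list(similarity.index)
    lab = labels.loc[samples].to_numpy()
    strat = (
        strata.loc[samples].to_numpy() if strata is not None else np.zeros(len(samples), dtype=int)
    )
    S = similarity.to_numpy(dtype=float)
    d_obs = _dissimilarity(S, lab)

    uniq = np.unique(lab)
    total = _count_labellings(lab, strat)
    if not force_random and len(uniq) == 2 and total <= n_perm:
        masks = _enumerate_two_group(lab, strat, uniq[0])
        count = 0
        for mask in masks:
            perm = np.where(mask, uniq[0], uniq[1])
            if _dissimilarity(S, perm) >= d_obs - 1e-12:
                count += 1
        logger.info(
            "%s: exact enumeration of %d labellings instead of %d permutations",
            label or "permutation test", total, n_perm,
        )
        return FingerprintTestResult(d=d_obs, p=count / total, n_perm=total, exact=True, label=label)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = lab.copy()
        for s in np.unique(strat):
            idx = np.flatnonzero(strat == s)
            perm[idx] = perm[rng.permutation(idx)]
        if _dissimilarity(S, perm) >= d_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return FingerprintTestResult(d=d_obs, p=p, n_perm=n_perm, exact=False, label=label)


# ---------------------------------------------------------------------------
# Study-shaped report
# ---------------------------------------------------------------------------


def multi_site_report(
    fingerprints: FingerprintSet,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    groups: Sequence[str] = DEFAULT_GROUPS,
    stratify_total: bool = True,
) -> pd.DataFrame:
    """Per-site IN-vs-OUT tests, a pooled site-stratified test, and an
    among-sites test, one row each.

    A site whose lanes all carry one group label is reported untestable.
    The pooled "Total" row permutes labels within sites when
    ``stratify_total`` (the default); the among-sites row uses the site
    as the grouping factor with global permutation.
    """
    design = fingerprints.design.loc[fingerprints.samples]
    sim = similarity_matrix(fingerprints)
    sites = list(dict.fromkeys(design["site"]))
    rows = []

    def emit(scope: str, res: Optional[FingerprintTestResult], note: str = "") -> None:
        if res is None:
            rows.append((scope, np.nan, np.nan, 0, False, False, note))
        else:
            rows.append((scope, res.d, res.p, res.n_perm, res.exact, res.p < alpha, note))

    for k, site in enumerate(sites):
        lanes = list(design.index[design["site"] == site])
        sub = design.loc[lanes]
        if sub["group"].nunique() < 2 or sub["group"].value_counts().min() < 2:
            emit(site, None, "untestable: need >= 2 lanes of each group")
            continue
        res = permutation_group_test(
            sim.loc[lanes, lanes], sub["group"], n_perm=n_perm, seed=None if seed is None else seed + k,
            label=site,
        )
        emit(site, res)

    res_total = permutation_group_test(
        sim, design["group"], n_perm=n_perm,
        seed=None if seed is None else seed + len(sites),
        strata=design["site"] if stratify_total else None, label="Total",
    )
    emit("Total", res_total)

    if len(sites) > 1:
        res_among = permutation_group_test(
            sim, design["site"], n_perm=n_perm,
            seed=None if seed is None else seed + len(sites) + 1, label="Among sites",
        )
        emit("Among sites", res_among)

    return pd.DataFrame(
        rows, columns=["scope", "d", "p", "n_perm", "exact", "significant", "note"]
    )


def fingerprint_report(
    by_taxon: Dict[str, FingerprintSet],
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    **kw,
) -> pd.DataFrame:
    """Tidy multi-taxon report (one fingerprint gel per targeted taxon)."""
    frames = []
    for taxon, fps in by_taxon.items():
        rep = multi_site_report(fps, n_perm=n_perm, seed=seed, alpha=alpha, **kw)
        rep.insert(0, "taxon", taxon)
        frames.append(rep)
    return pd.concat(frames, ignore_index=True)
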
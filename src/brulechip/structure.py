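"""Principal-component-based community-structure test per taxon.

For a taxon's standardised log-intensity submatrix, samples are the
observations and the taxon's OTUs the variables.  PCA retains the first
``n_pcs`` components; the test statistic is the eigenvalue-weighted
squared separation of the niche means in PC space,

    T = sum_k  w_k * (mean score_IN,k - mean score_OUT,k)^2 ,

with ``w_k`` the fraction of total variance carried by component ``k``.
The p-value is exact: every distinct relabelling of the samples into
groups of the observed sizes is enumerated (the PC scores stay fixed;
only the group means move), and p is the fraction of relabellings with
T at least the observed value, the observed labelling included.  For a
3v3 design this enumerates C(6,3) = 20 assignments — 10 distinct splits
— so the smallest attainable p is 0.1.

The statistic is one concrete instantiation of a first-3-PC group test;
it sits behind this single function so an alternative statistic can be
swapped in without touching callers.
"""

from __future__ import annotations

from itertools import combinations
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import DEFAULT_GROUPS, StructureTestResult, TaxonomyTable, group_samples

DEFAULT_MIN_OTUS = 10


def pc_scores(X: pd.DataFrame, n_pcs: int = 3) -> Tuple[np.ndarray, np.ndarray]:
    """Sample scores and variance fractions of the leading components.

    ``X`` is OTU x sample; observations are the samples.  Columns of the
    observation matrix are centred before the SVD (rows of ``X`` that
    are already standardised are unchanged by this).  Returns
    ``(scores, variance_fractions)`` for the first
    ``min(n_pcs, rank)`` components; raises if the matrix has rank 0.
    """
    M = X.to_numpy(dtype=float).T  # samples x otus
    M = M - M.mean(axis=0, keepdims=True)
    U, s, _Vt = np.linalg.svd(M, full_matrices=False)
    total = float((s**2).sum())
    rank = int((s > s.max() * 1e-12).sum()) if s.size and s.max() > 0 else 0
    if rank < 1:
        raise ValueError("matrix has rank < 1; no principal component to test")
    k = min(n_pcs, rank)
    scores = U[:, :k] * s[:k]
    varfrac = (s[:k] ** 2) / total
    return scores, varfrac


def _statistic(scores: np.ndarray, weights: np.ndarray, in_mask: np.ndarray) -> float:
    d = scores[in_mask].mean(axis=0) - scores[~in_mask].mean(axis=0)
    return float((weights * d**2).sum())


def taxon_structure_test(
    X: pd.DataFrame,
    design: pd.DataFrame,
    n_pcs: int = 3,
    min_otus: int = DEFAULT_MIN_OTUS,
    groups: Sequence[str] = DEFAULT_GROUPS,
) -> StructureTestResult:
    """Exact two-group PC test on one taxon's standardised submatrix.

    ``X`` is OTU x sample.  A taxon with fewer than ``min_otus`` OTUs is
    returned untested (``tested=False``) rather than raising, so rank
    sweeps can skip small taxa uniformly.
    """
    n_otus = X.shape[0]
    if n_otus < min_otus:
        return StructureTestResult(
            float("nan"), float("nan"), (), n_otus=n_otus, tested=False,
            note=f"fewer than {min_otus} OTUs",
        )
    members = group_samples(design.loc[X.columns], groups)
    n_in = len(members[groups[0]])
    n_out = len(members[groups[1]])
    if min(n_in, n_out) < 2:
        raise ValueError("need >= 2 samples per group")

    samples = list(X.columns)
    scores, varfrac = pc_scores(X, n_pcs=n_pcs)
    in_mask = np.array([s in set(members[groups[0]]) for s in samples])
    t_obs = _statistic(scores, varfrac, in_mask)

    n = len(samples)
    count = 0
    total = 0
    for combo in combinations(range(n), n_in):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        total += 1
        if _statistic(scores, varfrac, mask) >= t_obs - 1e-12:
            count += 1
    p = count / total
    n_splits = total // 2 if n_in == n_out else total
    return StructureTestResult(
        statistic=t_obs,
        p=p,
        variance_explained=tuple(float(v) for v in varfrac),
        n_splits=n_splits,
        n_otus=n_otus,
        tested=True,
    )


def structure_report(
    Z: pd.DataFrame,
    taxonomy: TaxonomyTable,
    design: pd.DataFrame,
    ranks: Sequence[str] = ("phylum", "class", "order", "family"),
    n_pcs: int = 3,
    min_otus: int = DEFAULT_MIN_OTUS,
    groups: Sequence[str] = DEFAULT_GROUPS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the PC test for every taxon at the requested ranks.

    ``Z`` is the full standardised log-intensity matrix (OTU x sample).
    Returns one row per (rank, taxon) with T, p, the retained variance
    fractions, and a tested/untested flag.
    """
    rows = []
    for rank in ranks:
        taxa = taxonomy.taxa_at(rank).reindex(Z.index)
        for taxon, otus in Z.index.groupby(taxa).items():
            res = taxon_structure_test(
                Z.loc[otus], design, n_pcs=n_pcs, min_otus=min_otus, groups=groups
            )
            var = list(res.variance_explained) + [np.nan] * (n_pcs - len(res.variance_explained))
            rows.append(
                (
                    rank, taxon, res.n_otus, res.tested, res.statistic, res.p,
                    *var[:n_pcs],
                    bool(res.tested and res.p < alpha),
                )
            )
    cols = ["rank", "taxon", "n_otus", "tested", "T", "p"] + [
        f"var_pc{k + 1}" for k in range(n_pcs)
    ] + ["significant"]
    return pd.DataFrame(rows, columns=cols)
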
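"""Discriminative-OTU detection from scaled intensities.

Pipeline: per-OTU trimmed-mean intensities are log10-transformed,
centred and standardised (mean 0, SD 1 across all samples); each OTU is
tested with an unadjusted pooled-variance two-sided t-test between the
two niches (exact at the balanced replicate design; Welch's form is
available behind a flag but conservative at n = 3 per group);
OTUs with p < alpha *and* at least a ``fold_min``-fold difference in
untransformed group means feed the heatmap; per-taxon counts of
IN-higher and OUT-higher OTUs summarise discriminative taxa.

The t statistic is invariant to the per-row affine standardisation, so
testing standardised values is equivalent to testing the log
intensities; standardisation is kept because the same matrix also feeds
PCA-based structure testing and heatmaps.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .model import DEFAULT_GROUPS, OtuCallTable, TaxonomyTable, RANKS, group_samples

logger = logging.getLogger(__name__)

DIRECTION_NONE = "none"

RESULT_COLUMNS = ["mean_log_in", "mean_log_out", "fold_change", "t", "p", "direction"]


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going up (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


def standardize_log(intensity: pd.DataFrame) -> Tuple[pd.DataFrame, Dict[str, List[str]]]:
    """log10-transform then z-score each OTU row across all samples.

    Rows with any nonpositive intensity (not log-transformable) or zero
    variance on the log scale are excluded; the returned dict reports
    them under the reasons ``nonpositive`` and ``zero_variance``.
    """
    excluded: Dict[str, List[str]] = {"nonpositive": [], "zero_variance": []}
    vals = intensity.to_numpy(dtype=float)
    pos = (vals > 0).all(axis=1)
    excluded["nonpositive"] = list(intensity.index[~pos])
    logv = np.log10(vals[pos])
    sd = logv.std(axis=1, ddof=1)
    keep = sd > 0
    excluded["zero_variance"] = list(intensity.index[pos][~keep])
    z = (logv[keep] - logv[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    for reason, otus in excluded.items():
        if otus:
            logger.info("standardize_log excluded %d OTUs (%s)", len(otus), reason)
    out = pd.DataFrame(z, index=intensity.index[pos][keep], columns=intensity.columns)
    return out, excluded


def per_otu_tests(
    intensity: pd.DataFrame,
    design: pd.DataFrame,
    alpha: float = 0.05,
    groups: Sequence[str] = DEFAULT_GROUPS,
    welch: bool = False,
) -> pd.DataFrame:
    """Two-sided t-test per OTU on standardised log intensities.

    ``intensity`` is the untransformed OTU x sample trimmed-mean matrix
    (typically restricted to detected OTUs).  Returns one row per
    testable OTU with the group log10 means, the fold-change as the
    ratio of *untransformed* group means, the t statistic, the
    unadjusted p, and the direction (first group higher / second group
    higher / none).  OTUs whose rows are excluded by standardisation, or
    with degenerate within-group variance, get direction ``none`` and
    NaN statistics.
    """
    members = group_samples(design.loc[intensity.columns], groups)
    for g, ss in members.items():
        if len(ss) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    z, _excluded = standardize_log(intensity)

    a = z[members[groups[0]]].to_numpy()
    b = z[members[groups[1]]].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=not welch)

    raw = intensity.loc[z.index]
    mean_in_raw = raw[members[groups[0]]].mean(axis=1)
    mean_out_raw = raw[members[groups[1]]].mean(axis=1)
    logr = np.log10(raw.to_numpy())
    mean_log_in = pd.Series(
        logr[:, [raw.columns.get_loc(s) for s in members[groups[0]]]].mean(axis=1), index=raw.index
    )
    mean_log_out = pd.Series(
        logr[:, [raw.columns.get_loc(s) for s in members[groups[1]]]].mean(axis=1), index=raw.index
    )

    res = pd.DataFrame(index=z.index.rename("otu_id"))
    res["mean_log_in"] = mean_log_in
    res["mean_log_out"] = mean_log_out
    res["fold_change"] = (mean_in_raw / mean_out_raw).to_numpy()
    res["t"] = t
    res["p"] = p
    higher_in = mean_log_in.to_numpy() > mean_log_out.to_numpy()
    sig = np.isfinite(p) & (p < alpha)
    res["direction"] = np.where(
        sig, np.where(higher_in, f"{groups[0]}-higher", f"{groups[1]}-higher"), DIRECTION_NONE
    )
    n_deg = int((~np.isfinite(p)).sum())
    if n_deg:
        logger.info("per_otu_tests: %d OTUs with undefined p (degenerate variance)", n_deg)

    # re-attach excluded OTUs so downstream totals still see them
    dropped = intensity.index.difference(z.index)
    if len(dropped):
        pad = pd.DataFrame(
            {
                "mean_log_in": np.nan, "mean_log_out": np.nan, "fold_change": np.nan,
                "t": np.nan, "p": np.nan, "direction": DIRECTION_NONE,
            },
            index=dropped.rename("otu_id"),
        )
        res = pd.concat([res, pad]).loc[intensity.index]
    res.attrs["alpha"] = alpha
    res.attrs["groups"] = tuple(groups)
    return res


def select_heatmap_otus(
    result: pd.DataFrame,
    intensity: pd.DataFrame,
    fold_min: float = 1.8,
    alpha: float = 0.05,
    taxonomy: Optional[TaxonomyTable] = None,
) -> Tuple[List[str], pd.DataFrame]:
    """OTUs with p < alpha (strict) and >= fold_min-fold mean difference.

    The fold filter is symmetric — ``max(fold, 1/fold) >= fold_min``,
    inclusive at the boundary — so it is direction-agnostic.  Returns
    the selected OTU ids and the corresponding untransformed intensity
    submatrix, ordered by taxonomy lineage (when given) then by
    decreasing symmetric fold-change.
    """
    fold = result["fold_change"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sym = np.maximum(fold, 1.0 / fold)
    # two-sided comparison keeps the inclusive boundary exact for a fold
    # of exactly fold_min in either direction (no 1/(1/x) round-trip)
    fold_ok = (fold >= fold_min) | (fold <= 1.0 / fold_min)
    mask = (result["p"].to_numpy() < alpha) & fold_ok
    mask &= np.isfinite(result["p"].to_numpy()) & np.isfinite(sym)
    selected = result.index[mask]
    logger.info("heatmap selection: %d OTUs at p<%g and fold>=%g", len(selected), alpha, fold_min)

    order = pd.DataFrame({"sym_fold": sym[mask]}, index=selected)
    if taxonomy is not None:
        lin = taxonomy.lineages.reindex(selected)
        order = pd.concat([lin, order], axis=1)
        order = order.sort_values(
            by=[*RANKS, "sym_fold"], ascending=[True] * len(RANKS) + [False], kind="mergesort"
        )
    else:
        order = order.sort_values("sym_fold", ascending=False, kind="mergesort")
    otus = list(order.index)
    return otus, intensity.loc[otus]


def discriminative_taxon_summary(
    result: pd.DataFrame,
    taxonomy: TaxonomyTable,
    ranks: Sequence[str] = ("phylum", "class", "order", "family", "genus"),
    groups: Sequence[str] = DEFAULT_GROUPS,
) -> pd.DataFrame:
    """Per-taxon counts and percentages of discriminative OTUs.

    ``n_in`` / ``n_out`` count OTUs whose intensity is significantly
    higher in the first / second niche; ``n_total`` counts all OTUs of
    the taxon in ``result`` (i.e. all detected OTUs).  Percentages are
    rounded half-up to integers.  Rows partition the OTUs at each rank:
    summing ``n_in`` over any single rank recovers the overall IN-higher
    count.
    """
    dir_in = (result["direction"] == f"{groups[0]}-higher")
    dir_out = (result["direction"] == f"{groups[1]}-higher")
    rows = []
    for rank in ranks:
        taxa = taxonomy.taxa_at(rank).reindex(result.index)
        n_total = taxa.value_counts()
        n_in = dir_in.groupby(taxa).sum().reindex(n_total.index, fill_value=0)
        n_out = dir_out.groupby(taxa).sum().reindex(n_total.index, fill_value=0)
        for taxon in n_total.index:
            tot = int(n_total[taxon])
            rows.append(
                (
                    rank, taxon, int(n_in[taxon]), int(n_out[taxon]), tot,
                    round_half_up(100.0 * n_in[taxon] / tot) if tot else 0,
                    round_half_up(100.0 * n_out[taxon] / tot) if tot else 0,
                )
            )
    return pd.DataFrame(
        rows, columns=["rank", "taxon", "n_in", "n_out", "n_total", "pct_in", "pct_out"]
    )


def plot_heatmap(submatrix: pd.DataFrame, path) -> None:
    """Render the untransformed-intensity heatmap of selected OTUs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(2 + 0.5 * submatrix.shape[1], 1 + 0.18 * max(1, submatrix.shape[0]))
    )
    im = ax.imshow(np.log10(submatrix.to_numpy() + 1.0), aspect="auto", cmap="viridis")
    ax.set_xticks(range(submatrix.shape[1]), submatrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(submatrix.shape[0]), submatrix.index, fontsize=4)
    fig.colorbar(im, ax=ax, label="log10 intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
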
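"""Per-taxon relative-richness tables and OTU overlap summaries.

Relative richness is the number of OTUs called present per sample,
compared between the two niches taxon by taxon.  The table mirrors the
published layout: the most OTU-rich bacterial taxa as named rows, an
``others`` bucket for the rest, and Archaea collapsed into a single row.
Group means +/- sample standard deviations are tested per taxon with a
pooled-variance two-sided t-test, which is exact under the null at the
balanced 3v3 design (Welch's unequal-variance form is available behind
a flag but is markedly conservative at n = 3 per group); p-values are
reported unadjusted by default, with multiple-testing correction
available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .model import DOMAIN_ARCHAEA, DEFAULT_GROUPS, OtuCallTable, TaxonomyTable, group_samples

logger = logging.getLogger(__name__)

ARCHAEA_ROW = "Archaea"
OTHERS_ROW = "others"


def two_group_ttest(a: np.ndarray, b: np.ndarray, welch: bool = False) -> Tuple[float, float]:
    """Two-sided t-test returning (t, p); degenerate inputs never raise.

    When both groups have zero variance the test is decided by the
    means: equal means give p = 1 (logged by callers), unequal means
    give p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


@dataclass
class OverlapSummary:
    """Fractions (percent) of detected OTUs shared across niches/samples."""

    pct_both_groups: float
    pct_all_samples: float
    n_detected: int


def overlap_summary(
    calls: OtuCallTable,
    design: pd.DataFrame,
    groups: Sequence[str] = DEFAULT_GROUPS,
) -> OverlapSummary:
    """Percent of detected OTUs present in both niches / in every sample."""
    presence = calls.presence()
    detected = presence.any(axis=1)
    n_det = int(detected.sum())
    if n_det == 0:
        raise ValueError("no OTU detected in any sample")
    members = group_samples(design.loc[presence.columns], groups)
    in_both = presence[members[groups[0]]].any(axis=1) & presence[members[groups[1]]].any(axis=1)
    in_all = presence.all(axis=1)
    return OverlapSummary(
        pct_both_groups=100.0 * float(in_both.sum()) / n_det,
        pct_all_samples=100.0 * float(in_all.sum()) / n_det,
        n_detected=n_det,
    )


def richness_table(
    calls: OtuCallTable,
    taxonomy: TaxonomyTable,
    design: pd.DataFrame,
    rank: str = "phylum",
    groups: Sequence[str] = DEFAULT_GROUPS,
    top_n: Optional[int] = 12,
    alpha: float = 0.05,
    welch: bool = False,
    adjust: Optional[str] = None,
) -> pd.DataFrame:
    """Detected-OTU counts per taxon with per-taxon two-group t-tests.

    Rows: the ``top_n`` bacterial taxa at ``rank`` by union total, an
    ``others`` bucket for the remainder, and one collapsed ``Archaea``
    row.  Columns: per-group mean and SD of per-sample detected-OTU
    counts, the union total (OTUs detected in >= 1 of all samples), the
    t statistic, its (optionally adjusted) two-sided p-value, and a
    significance flag at ``alpha``.  Union totals across rows sum to
    the overall number of detected OTUs (the rows partition the OTUs).
    """
    presence = calls.presence()
    presence = presence.loc[:, [s for s in presence.columns]]
    missing = [o for o in presence.index if o not in taxonomy.otu_ids]
    if missing:
        raise ValueError(f"{len(missing)} called OTUs missing from taxonomy, e.g. {missing[0]!r}")
    members = group_samples(design.loc[presence.columns], groups)
    for g, ss in members.items():
        if len(ss) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")

    taxa = taxonomy.taxa_at(rank).reindex(presence.index)
    domains = taxonomy.domains().reindex(presence.index)
    taxa = taxa.mask(domains == DOMAIN_ARCHAEA, ARCHAEA_ROW)

    counts = presence.groupby(taxa).sum()  # taxon x sample detected counts
    totals = presence.any(axis=1).groupby(taxa).sum().astype(int)

    bacterial = totals.drop(index=ARCHAEA_ROW, errors="ignore").sort_values(
        ascending=False, kind="mergesort"
    )
    if top_n is not None and len(bacterial) > top_n:
        named = list(bacterial.index[:top_n])
        bucket = [t for t in bacterial.index if t not in named]
    else:
        named = list(bacterial.index)
        bucket = []

    def row_counts(taxon_list: Sequence[str]) -> pd.Series:
        return counts.loc[list(taxon_list)].sum(axis=0)

    rows = []
    order = named + ([OTHERS_ROW] if bucket else []) + (
        [ARCHAEA_ROW] if ARCHAEA_ROW in totals.index else []
    )
    for name in order:
        if name == OTHERS_ROW:
            c = row_counts(bucket)
            total = int(totals[bucket].sum())
        else:
            c = counts.loc[name]
            total = int(totals[name])
        a = c[members[groups[0]]].to_numpy(dtype=float)
        b = c[members[groups[1]]].to_numpy(dtype=float)
        t, p = two_group_ttest(a, b, welch=welch)
        if p == 1.0 and t == 0.0:
            logger.info("taxon %r: identical counts in both groups, p set to 1", name)
        rows.append(
            (
                name,
                a.mean(), a.std(ddof=1), b.mean(), b.std(ddof=1),
                total, t, p,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "taxon",
            f"mean_{groups[0].lower()}", f"sd_{groups[0].lower()}",
            f"mean_{groups[1].lower()}", f"sd_{groups[1].lower()}",
            "total", "t", "p",
        ],
    ).set_index("taxon")
    if adjust:
        from statsmodels.stats.multitest import multipletests

        out["p"] = multipletests(out["p"].to_numpy(), method=adjust)[1]
    out["significant"] = out["p"] < alpha
    out.attrs["rank"] = rank
    out.attrs["overall_total"] = int(presence.any(axis=1).sum())
    return out
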
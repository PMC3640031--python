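"""Probe-level intensities → per-sample OTU presence calls and intensities.

The calling procedure has three parts:

1. **Spike rescaling** — every sample's intensities are multiplied by
   (grand mean of per-sample spike means) / (that sample's spike mean),
   so the spiked internal-standard probes end up with equal means across
   arrays and OTU intensities become comparable between samples.
2. **Stage 1** — per OTU and sample, each PM/MM pair gets the response
   score ``r = max(0, (PM - MM) / (PM + MM))``; a pair is *usable* when
   its PM exceeds the array's background level (a low quantile of all
   probe intensities on that array) and, if configured, sits below a
   saturation ceiling.  The probe-set summary (pairs_counted,
   pairs_scored, q1/q2/q3 = 25/50/75th percentiles of usable scores) is
   compared against domain-specific cutoffs, all inclusive (``>=``):
   bacteria require pairs_counted >= 7, pairs_scored >= 7, q1 >= 0.5,
   q2 >= 0.93, q3 >= 0.98; archaea use loosened cutoffs q2 >= 0.8 and
   q3 >= 0.9 but only for OTUs whose trimmed-mean intensity reaches
   1000 units in at least one sample.
3. **Stage 2** — each Stage-1-present OTU is penalised for
   cross-hybridisation: pairs shared with another OTU that is also
   Stage-1-present in the same sample are removed and q3 is recomputed
   on the remaining usable pairs; the OTU keeps its call only if the
   adjusted q3 stays >= 0.1.

The per-OTU intensity reported alongside the calls is the trimmed mean
of the probe set's PM intensities (single highest and lowest removed).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .model import (
    ArrayExperiment,
    CALL_COLUMNS,
    DOMAIN_ARCHAEA,
    DOMAIN_BACTERIA,
    OtuCallTable,
    ProbeLibrary,
    Stage1Metrics,
)

logger = logging.getLogger(__name__)


@dataclass
class BacteriaThresholds:
    min_pairs_counted: int = 7
    min_pairs_scored: int = 7
    q1_min: float = 0.5
    q2_min: float = 0.93
    q3_min: float = 0.98


@dataclass
class ArchaeaThresholds:
    q2_min: float = 0.8
    q3_min: float = 0.9
    min_trimmed_mean: float = 1000.0


@dataclass
class CallingThresholds:
    """All cutoffs of the two-stage calling procedure (defaults as printed)."""

    bacteria: BacteriaThresholds = field(default_factory=BacteriaThresholds)
    archaea: ArchaeaThresholds = field(default_factory=ArchaeaThresholds)
    stage2_q3_min: float = 0.1
    background_quantile: float = 0.02
    saturation_value: Optional[float] = None

    def __post_init__(self) -> None:
        for q in (self.bacteria.q1_min, self.bacteria.q2_min, self.bacteria.q3_min,
                  self.archaea.q2_min, self.archaea.q3_min, self.stage2_q3_min):
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"quantile cutoff {q} outside [0, 1]")
        if not 0.0 <= self.background_quantile < 1.0:
            raise ValueError("background_quantile must lie in [0, 1)")

    @classmethod
    def from_dict(cls, data: Mapping) -> "CallingThresholds":
        data = dict(data)
        bact = BacteriaThresholds(**data.pop("bacteria", {}))
        arch = ArchaeaThresholds(**data.pop("archaea", {}))
        return cls(bacteria=bact, archaea=arch, **data)

    @classmethod
    def from_yaml(cls, path) -> "CallingThresholds":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# Spike rescaling
# ---------------------------------------------------------------------------


def spike_scale_factors(experiment: ArrayExperiment, library: ProbeLibrary) -> pd.Series:
    """Per-sample multipliers equalising spike-probe means across arrays."""
    if not library.spike_probes:
        raise ValueError("probe library has no spike probes; cannot scale")
    spikes = experiment.intensities.loc[library.spike_probes]
    means = spikes.mean(axis=0)
    if (means <= 0).any():
        bad = list(means.index[means <= 0])
        raise ValueError(f"nonpositive spike mean in samples {bad}")
    return (means.mean() / means).rename("scale_factor")


def spike_scale(experiment: ArrayExperiment, library: ProbeLibrary) -> ArrayExperiment:
    """Rescale every sample so that per-sample spike means coincide.

    Idempotent: a second application finds all factors equal to 1.
    """
    factors = spike_scale_factors(experiment, library)
    logger.info("spike scale factors: %s", factors.round(4).to_dict())
    scaled = experiment.intensities.mul(factors, axis=1)
    return ArrayExperiment(scaled, experiment.design, experiment.domain_label)


# ---------------------------------------------------------------------------
# Pair scores and probe-set metrics
# ---------------------------------------------------------------------------


def response_scores(
    pm: np.ndarray,
    mm: np.ndarray,
    background: float | np.ndarray,
    saturation: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Clipped PM/MM contrast scores and usability masks.

    Returns ``(scores, usable, scored)``; a score is NaN (pair not
    scorable) when PM + MM = 0.
    """
    pm = np.asarray(pm, dtype=float)
    mm = np.asarray(mm, dtype=float)
    total = pm + mm
    safe = np.where(total > 0, total, 1.0)
    scores = np.where(total > 0, np.clip((pm - mm) / safe, 0.0, None), np.nan)
    usable = pm > background
    if saturation is not None:
        usable = usable & (pm < saturation)
    scored = usable & np.isfinite(scores)
    return scores, usable, scored


def stage1_metrics(scores: np.ndarray, usable: np.ndarray) -> Stage1Metrics:
    """Summarise one probe set's usable pair scores (never raises on empties)."""
    scores = np.asarray(scores, dtype=float)
    usable = np.asarray(usable, dtype=bool)
    scored = usable & np.isfinite(scores)
    vals = scores[scored]
    if vals.size:
        q1, q2, q3 = np.percentile(vals, [25.0, 50.0, 75.0])
    else:
        q1 = q2 = q3 = float("nan")
    return Stage1Metrics(int(usable.sum()), int(scored.sum()), float(q1), float(q2), float(q3))


def stage1_call(
    metrics: Stage1Metrics,
    domain: str,
    thresholds: CallingThresholds,
    archaea_eligible: bool = True,
) -> bool:
    """Apply the domain's Stage-1 cutoffs (all comparisons inclusive).

    ``archaea_eligible`` carries the OTU-level intensity gate: an
    archaeal OTU is only considered when some sample's trimmed-mean
    intensity reaches the configured floor.
    """
    if domain == DOMAIN_BACTERIA:
        t = thresholds.bacteria
        return bool(
            metrics.pairs_counted >= t.min_pairs_counted
            and metrics.pairs_scored >= t.min_pairs_scored
            and np.isfinite(metrics.q1)
            and metrics.q1 >= t.q1_min
            and metrics.q2 >= t.q2_min
            and metrics.q3 >= t.q3_min
        )
    if domain == DOMAIN_ARCHAEA:
        t = thresholds.archaea
        return bool(
            archaea_eligible
            and np.isfinite(metrics.q2)
            and metrics.q2 >= t.q2_min
            and metrics.q3 >= t.q3_min
        )
    raise ValueError(f"unknown domain label {domain!r}")


def trimmed_mean(values: np.ndarray) -> float:
    """Mean after removing exactly one maximum and one minimum occurrence.

    With fewer than 3 values the plain mean is returned (and logged by
    the pipeline); empty input is an error.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("trimmed mean of empty input")
    if values.size < 3:
        return float(values.mean())
    return float((values.sum() - values.max() - values.min()) / (values.size - 2))


def adjusted_q3(scores: np.ndarray, usable: np.ndarray, flagged: np.ndarray) -> float:
    """q3 recomputed over unflagged usable pairs; 0 when none remain."""
    keep = usable & np.isfinite(scores) & ~flagged
    if not keep.any():
        return 0.0
    return float(np.percentile(scores[keep], 75.0))


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def call_otus(
    experiment: ArrayExperiment,
    library: ProbeLibrary,
    thresholds: Optional[CallingThresholds] = None,
    spike_scaled: bool = False,
) -> OtuCallTable:
    """Run spike scaling, Stage 1 and the Stage 2 cross-hyb penalty.

    Domain labels come from ``experiment.domain_label`` (OTUs without a
    label are treated as bacteria).  Set ``spike_scaled=True`` when the
    matrix has already been rescaled.
    """
    thr = thresholds or CallingThresholds()
    logger.info(
        "calling thresholds: bacteria=%s archaea=%s stage2_q3_min=%s background_quantile=%s saturation=%s",
        dataclasses.asdict(thr.bacteria), dataclasses.asdict(thr.archaea),
        thr.stage2_q3_min, thr.background_quantile, thr.saturation_value,
    )
    exp = experiment if spike_scaled else spike_scale(experiment, library)
    exp.check_library(library)

    idx = library.probe_index()
    samples = exp.samples
    n_samp = len(samples)
    pm_mat = exp.intensities.loc[idx["pm"]].to_numpy()
    mm_mat = exp.intensities.loc[idx["mm"]].to_numpy()
    background = np.quantile(exp.intensities.to_numpy(), thr.background_quantile, axis=0)
    scores, usable, _scored = response_scores(pm_mat, mm_mat, background, thr.saturation_value)

    groups: Dict[str, np.ndarray] = idx.groupby("otu_id", sort=False).indices
    domains = exp.domain_label
    small_sets = []

    otu_ids = list(groups)
    metrics: Dict[str, list] = {o: [] for o in otu_ids}
    tmeans = np.zeros((len(otu_ids), n_samp))
    stage1 = np.zeros((len(otu_ids), n_samp), dtype=bool)

    for oi, otu in enumerate(otu_ids):
        rows = groups[otu]
        pm_o = pm_mat[rows]
        n = pm_o.shape[0]
        if n >= 3:
            tmeans[oi] = (pm_o.sum(axis=0) - pm_o.max(axis=0) - pm_o.min(axis=0)) / (n - 2)
        else:
            tmeans[oi] = pm_o.mean(axis=0)
            small_sets.append(otu)
        domain = DOMAIN_BACTERIA
        if domains is not None and otu in domains.index:
            domain = str(domains[otu])
        eligible = True
        if domain == DOMAIN_ARCHAEA:
            eligible = bool(tmeans[oi].max() >= thr.archaea.min_trimmed_mean)
        for s in range(n_samp):
            m = stage1_metrics(scores[rows, s], usable[rows, s])
            metrics[otu].append(m)
            stage1[oi, s] = stage1_call(m, domain, thr, archaea_eligible=eligible)
    if small_sets:
        logger.info("plain mean used for %d probe sets with < 3 pairs", len(small_sets))

    # Stage 2: penalise pairs shared with co-present neighbours
    otu_pos = {o: i for i, o in enumerate(otu_ids)}
    pair_arrays = {o: idx["pair_id"].to_numpy()[groups[o]] for o in otu_ids}
    present = stage1.copy()
    q3_adj = np.array([[metrics[o][s].q3 for s in range(n_samp)] for o in otu_ids])

    for oi, otu in enumerate(otu_ids):
        neigh = library.neighbors(otu)
        if not neigh:
            continue
        rows = groups[otu]
        pairs = pair_arrays[otu]
        for s in range(n_samp):
            if not stage1[oi, s]:
                continue
            flagged_ids: set = set()
            for other, shared in neigh.items():
                if other in otu_pos and stage1[otu_pos[other], s]:
                    flagged_ids |= set(shared)
            if not flagged_ids:
                continue
            flagged = np.isin(pairs, list(flagged_ids))
            q3_adj[oi, s] = adjusted_q3(scores[rows, s], usable[rows, s], flagged)
            if q3_adj[oi, s] < thr.stage2_q3_min:
                present[oi, s] = False
                logger.debug(
                    "stage2 removed %s in %s (q3_adjusted=%.3f < %.3f)",
                    otu, samples[s], q3_adj[oi, s], thr.stage2_q3_min,
                )

    records = []
    for oi, otu in enumerate(otu_ids):
        for s, sample in enumerate(samples):
            m = metrics[otu][s]
            records.append(
                (
                    otu, sample, bool(present[oi, s]), float(tmeans[oi, s]),
                    m.pairs_counted, m.pairs_scored, m.q1, m.q2, m.q3,
                    float(q3_adj[oi, s]), bool(stage1[oi, s]),
                )
            )
    calls = pd.DataFrame(records, columns=CALL_COLUMNS)
    return OtuCallTable(calls)
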
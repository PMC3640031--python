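"""Core domain types shared by every analysis stage.

The package compares microbial communities between two soil niches
(default labels ``IN`` and ``OUT`` — inside and outside a truffle brûlé)
using two kinds of measurements:

* phylogenetic-microarray probe intensities, where each operational
  taxonomic unit (OTU) is represented by a probe set of perfect-match /
  mismatch (PM/MM) probe pairs plus spiked internal-standard probes used
  for array-to-array intensity scaling; and
* gel-fingerprint lane profiles — intensity sampled along a normalised
  migration axis, one lane per sample.

Tabular data are carried as pandas objects; the dataclasses here mostly
attach the structural invariants that the downstream statistics rely on
(unique probe ids, complete PM/MM pairs, 6-slot lineages, aligned sample
designs) and raise :class:`FormatError` when a file or constructor
argument violates them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

#: Taxonomic ranks carried for every OTU, outermost first.  Species-level
#: identity is the OTU itself, so lineages stop at genus.
RANKS: Tuple[str, ...] = ("domain", "phylum", "class", "order", "family", "genus")

#: Greengenes-style single-letter rank prefixes, aligned with :data:`RANKS`.
RANK_PREFIXES: Tuple[str, ...] = ("k__", "p__", "c__", "o__", "f__", "g__")

DEFAULT_GROUPS: Tuple[str, str] = ("IN", "OUT")

DOMAIN_BACTERIA = "bacteria"
DOMAIN_ARCHAEA = "archaea"


class FormatError(ValueError):
    """A file or in-memory table violates the structural contract."""


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


def parse_lineage(text: str) -> Tuple[str, ...]:
    """Parse a semicolon-joined, rank-prefixed lineage into 6 rank slots.

    Missing trailing ranks are filled with empty strings (meaning
    "unclassified at that rank").  More than 6 fields, or a field whose
    prefix does not match its position, is a :class:`FormatError`.
    """
    parts = [p.strip() for p in text.split(";")] if text.strip() else []
    if len(parts) > len(RANKS):
        raise FormatError(f"lineage has {len(parts)} ranks, at most {len(RANKS)} allowed: {text!r}")
    out: List[str] = []
    for i, part in enumerate(parts):
        prefix = RANK_PREFIXES[i]
        if not part.startswith(prefix):
            raise FormatError(f"rank {i} of lineage {text!r} must start with {prefix!r}")
        out.append(part[len(prefix):])
    out.extend([""] * (len(RANKS) - len(out)))
    return tuple(out)


def format_lineage(slots: Sequence[str]) -> str:
    if len(slots) != len(RANKS):
        raise FormatError(f"lineage must have exactly {len(RANKS)} slots, got {len(slots)}")
    return ";".join(pref + slot for pref, slot in zip(RANK_PREFIXES, slots))


@dataclass
class TaxonomyTable:
    """OTU → 6-rank lineage table (domain, phylum, class, order, family, genus).

    ``lineages`` is indexed by ``otu_id`` with one column per rank; an
    empty string marks a rank at which the OTU is unclassified.
    Aggregation at any rank partitions the OTU set: an OTU unclassified
    at a rank is assigned to the synthetic taxon
    ``"unclassified <nearest named ancestor>"``.
    """

    lineages: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.lineages
        if tuple(df.columns) != RANKS:
            raise FormatError(f"taxonomy columns must be {RANKS}, got {tuple(df.columns)}")
        if not df.index.is_unique:
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate otu_id in taxonomy: {dup!r}")
        if df.isna().any().any():
            raise FormatError("taxonomy lineages may not contain missing values (use '')")

    @property
    def otu_ids(self) -> pd.Index:
        return self.lineages.index

    def domains(self) -> pd.Series:
        """Per-OTU domain label, lower-cased ('bacteria' / 'archaea' / ...)."""
        return self.lineages["domain"].str.lower().rename("domain")

    def taxa_at(self, rank: str) -> pd.Series:
        """Per-OTU taxon label at ``rank``; partitions the OTU set.

        Unclassified slots collapse into an ``unclassified <parent>``
        taxon keyed by the nearest named ancestor, so two OTUs that are
        unclassified under different parents land in different taxa.
        """
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        upto = RANKS[: RANKS.index(rank) + 1]
        sub = self.lineages[list(upto)]

        def label(row: pd.Series) -> str:
            if row.iloc[-1]:
                return row.iloc[-1]
            named = [v for v in row if v]
            return f"unclassified {named[-1]}" if named else "unclassified"

        return sub.apply(label, axis=1).rename(rank)

    def __len__(self) -> int:
        return len(self.lineages)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TaxonomyTable) and self.lineages.equals(other.lineages)


# ---------------------------------------------------------------------------
# Probe library
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbePair:
    """One perfect-match / mismatch probe pair within an OTU's probe set."""

    pair_id: str
    pm_probe_id: str
    mm_probe_id: str

    def __post_init__(self) -> None:
        if self.pm_probe_id == self.mm_probe_id:
            raise FormatError(f"pair {self.pair_id!r}: PM and MM probe ids must differ")


@dataclass
class ProbeLibrary:
    """OTU probe sets, spike-in probes and cross-hybridisation adjacency.

    ``crosshyb`` maps an unordered OTU pair (stored as a sorted tuple) to
    the set of ``pair_id`` values the two probe sets share — pairs whose
    probes respond to either OTU's 16S target and are therefore penalised
    when both OTUs appear present in the same sample.
    """

    probe_sets: Dict[str, List[ProbePair]]
    spike_probes: List[str] = field(default_factory=list)
    crosshyb: Dict[Tuple[str, str], FrozenSet[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen_probe: set = set()
        for otu, pairs in self.probe_sets.items():
            if not pairs:
                raise FormatError(f"probe set {otu!r} has no probe pairs")
            pair_ids = [p.pair_id for p in pairs]
            if len(set(pair_ids)) != len(pair_ids):
                raise FormatError(f"probe set {otu!r} has duplicate pair ids")
            for p in pairs:
                for pid in (p.pm_probe_id, p.mm_probe_id):
                    if pid in seen_probe:
                        raise FormatError(f"duplicate probe_id {pid!r}")
                    seen_probe.add(pid)
        for pid in self.spike_probes:
            if pid in seen_probe:
                raise FormatError(f"spike probe {pid!r} collides with an OTU probe id")
        if len(set(self.spike_probes)) != len(self.spike_probes):
            raise FormatError("duplicate spike probe ids")
        for (a, b), shared in self.crosshyb.items():
            if a >= b:
                raise FormatError(f"crosshyb key ({a!r}, {b!r}) must be sorted and distinct")
            for otu in (a, b):
                if otu not in self.probe_sets:
                    raise FormatError(f"crosshyb references unknown OTU {otu!r}")
            for pid in shared:
                for otu in (a, b):
                    if pid not in {p.pair_id for p in self.probe_sets[otu]}:
                        raise FormatError(
                            f"crosshyb pair {pid!r} absent from probe set {otu!r}"
                        )

    @property
    def otu_ids(self) -> List[str]:
        return list(self.probe_sets)

    def neighbors(self, otu: str) -> Dict[str, FrozenSet[str]]:
        """Cross-hybridising neighbours of ``otu`` and the shared pair ids."""
        out: Dict[str, FrozenSet[str]] = {}
        for (a, b), shared in self.crosshyb.items():
            if a == otu:
                out[b] = shared
            elif b == otu:
                out[a] = shared
        return out

    def probe_index(self) -> pd.DataFrame:
        """Long table of (otu_id, pair_id, pm, mm) rows in library order."""
        rows = [
            (otu, p.pair_id, p.pm_probe_id, p.mm_probe_id)
            for otu, pairs in self.probe_sets.items()
            for p in pairs
        ]
        return pd.DataFrame(rows, columns=["otu_id", "pair_id", "pm", "mm"])

    def all_probe_ids(self) -> List[str]:
        idx = self.probe_index()
        return list(idx["pm"]) + list(idx["mm"]) + list(self.spike_probes)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ProbeLibrary)
            and self.probe_sets == other.probe_sets
            and self.spike_probes == other.spike_probes
            and self.crosshyb == other.crosshyb
        )


# ---------------------------------------------------------------------------
# Sample design
# ---------------------------------------------------------------------------


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check a sample design table (index sample_id; group, site, pool)."""
    for col in ("group", "site", "pool"):
        if col not in design.columns:
            raise FormatError(f"design table missing column {col!r}")
    if not design.index.is_unique:
        raise FormatError("duplicate sample_id in design table")
    return design


def group_samples(design: pd.DataFrame, groups: Sequence[str]) -> Dict[str, List[str]]:
    """Samples per group label, in design order; errors on unknown labels."""
    known = set(design["group"])
    missing = [g for g in groups if g not in known]
    if missing:
        raise ValueError(f"group labels {missing} absent from design (has {sorted(known)})")
    return {g: list(design.index[design["group"] == g]) for g in groups}


# ---------------------------------------------------------------------------
# Array experiment
# ---------------------------------------------------------------------------


@dataclass
class ArrayExperiment:
    """Probe × sample intensity matrix plus sample design.

    ``intensities`` is indexed by probe_id with one column per sample;
    ``design`` is indexed by sample_id with columns group/site/pool.
    ``domain_label`` optionally maps otu_id → 'bacteria'/'archaea' and is
    consulted by the calling stage to pick threshold sets.
    """

    intensities: pd.DataFrame
    design: pd.DataFrame
    domain_label: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        validate_design(self.design)
        m = self.intensities
        if not m.index.is_unique:
            raise FormatError("duplicate probe_id rows in intensity matrix")
        if m.isna().any().any():
            raise FormatError("intensity matrix has missing cells")
        if (m.to_numpy() < 0).any():
            raise FormatError("negative intensity encountered")
        unknown = [s for s in m.columns if s not in self.design.index]
        if unknown:
            raise FormatError(f"samples {unknown} present in matrix but absent from design")

    @property
    def samples(self) -> List[str]:
        return list(self.intensities.columns)

    def check_library(self, library: ProbeLibrary) -> None:
        """Every library probe must appear exactly once as a matrix row."""
        missing = [p for p in library.all_probe_ids() if p not in self.intensities.index]
        if missing:
            raise FormatError(f"{len(missing)} library probes missing from matrix, e.g. {missing[0]!r}")

    def subset_design(self) -> pd.DataFrame:
        return self.design.loc[self.samples]


# ---------------------------------------------------------------------------
# Calling results
# ---------------------------------------------------------------------------


@dataclass
class Stage1Metrics:
    """Per (OTU, sample) probe-set summary feeding the presence cutoffs.

    ``pairs_counted`` — usable pairs (above background, unsaturated);
    ``pairs_scored`` — usable pairs with a defined response score;
    ``q1/q2/q3`` — 25/50/75th percentiles (linear interpolation) of the
    usable response scores, NaN when no pair is scorable.
    """

    pairs_counted: int
    pairs_scored: int
    q1: float
    q2: float
    q3: float

    def __post_init__(self) -> None:
        if not 0 <= self.pairs_scored <= self.pairs_counted:
            raise ValueError("need 0 <= pairs_scored <= pairs_counted")
        qs = (self.q1, self.q2, self.q3)
        if all(math.isfinite(q) for q in qs) and not (self.q1 <= self.q2 + 1e-12 and self.q2 <= self.q3 + 1e-12):
            raise ValueError("quantiles must satisfy q1 <= q2 <= q3")


CALL_COLUMNS = [
    "otu_id",
    "sample",
    "present",
    "trimmed_mean_intensity",
    "pairs_counted",
    "pairs_scored",
    "q1",
    "q2",
    "q3",
    "q3_adjusted",
    "stage1_present",
]


@dataclass
class OtuCallTable:
    """Long-form per-(OTU, sample) presence calls and scaled intensities."""

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("otu_id", "sample", "present", "trimmed_mean_intensity") if c not in self.calls.columns]
        if missing:
            raise FormatError(f"call table missing columns {missing}")
        bad = self.calls["present"] & ~np.isfinite(self.calls["trimmed_mean_intensity"])
        if bad.any():
            raise FormatError("present call with non-finite trimmed-mean intensity")

    @classmethod
    def from_presence(
        cls, presence: pd.DataFrame, intensity: Optional[pd.DataFrame] = None
    ) -> "OtuCallTable":
        """Build a minimal call table from an OTU × sample boolean matrix."""
        if intensity is None:
            intensity = presence.astype(float)
        long = presence.stack().rename("present").reset_index()
        long.columns = ["otu_id", "sample", "present"]
        long["trimmed_mean_intensity"] = intensity.stack().to_numpy()
        return cls(long)

    def presence(self) -> pd.DataFrame:
        """OTU × sample boolean presence matrix."""
        return (
            self.calls.pivot(index="otu_id", columns="sample", values="present")
            .fillna(False)
            .astype(bool)
        )

    def intensity(self) -> pd.DataFrame:
        """OTU × sample matrix of spike-scaled trimmed-mean intensities."""
        return self.calls.pivot(index="otu_id", columns="sample", values="trimmed_mean_intensity")

    def detected(self) -> pd.Index:
        """OTUs present in at least one sample."""
        pres = self.presence()
        return pres.index[pres.any(axis=1)]


# ---------------------------------------------------------------------------
# Fingerprints
# ---------------------------------------------------------------------------


@dataclass
class FingerprintSet:
    """Lane profiles on a shared migration grid plus the sample design.

    ``lanes`` is indexed by migration position (monotone, in [0, 1]) with
    one column per sample.
    """

    lanes: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        validate_design(self.design)
        if len(self.lanes.index) < 2:
            raise FormatError("fingerprint grid must have at least 2 positions")
        if (self.lanes.to_numpy() < 0).any():
            raise FormatError("fingerprint intensities must be nonnegative")
        unknown = [s for s in self.lanes.columns if s not in self.design.index]
        if unknown:
            raise FormatError(f"lanes {unknown} absent from design")

    @property
    def samples(self) -> List[str]:
        return list(self.lanes.columns)

    def subset(self, samples: Sequence[str]) -> "FingerprintSet":
        return FingerprintSet(self.lanes[list(samples)], self.design.loc[list(samples)])


# ---------------------------------------------------------------------------
# Test results
# ---------------------------------------------------------------------------


@dataclass
class FingerprintTestResult:
    """Permutation-test outcome on a fingerprint similarity matrix.

    ``d`` is the percent-dissimilarity statistic: mean within-group minus
    mean between-group similarity, in percent points.  ``exact`` records
    whether the null was enumerated rather than sampled.
    """

    d: float
    p: float
    n_perm: int
    exact: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p must lie in (0, 1], got {self.p}")
        if self.p < 1.0 / (self.n_perm + 1) - 1e-12:
            raise ValueError("p below the permutation resolution 1/(n_perm+1)")


@dataclass
class StructureTestResult:
    """Principal-component community-structure test outcome for one taxon."""

    statistic: float
    p: float
    variance_explained: Tuple[float, ...]
    n_splits: int = 0
    n_otus: int = 0
    tested: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if self.tested:
            if not (0.0 < self.p <= 1.0):
                raise ValueError(f"p must lie in (0, 1], got {self.p}")
            if sum(self.variance_explained) > 1.0 + 1e-9:
                raise ValueError("variance fractions sum above 1")
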
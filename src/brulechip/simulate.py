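"""Synthetic array and fingerprint experiments with known ground truth.

The generator emulates the two experimental arms of a two-niche soil
survey:

* the **array arm** — one site, three replicate soil-DNA pools inside the
  brûlé and three outside, hybridised to a phylogenetic microarray whose
  OTU probe sets are PM/MM pairs, with spiked internal-standard probes
  and a per-array scale factor emulating hybridisation/scan variation;
* the **fingerprint arm** — four sites, four replicate lanes per niche
  per site, each lane a sum of Gaussian band profiles whose per-band
  presence probability may differ between niches.

Intensities use multiplicative lognormal noise (fluorescence is positive
and right-skewed); an MM probe sees its own background plus a small leak
fraction of the PM target signal, which makes the PM/MM response score's
ceiling tunable.  Everything is driven by one ``numpy`` Generator seeded
from :attr:`SimulationConfig.seed`, so a fixed seed gives byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .model import (
    ArrayExperiment,
    DOMAIN_ARCHAEA,
    DOMAIN_BACTERIA,
    FingerprintSet,
    ProbeLibrary,
    ProbePair,
    TaxonomyTable,
    RANKS,
)
from . import io as bio


@dataclass
class SimulationConfig:
    """Knobs of the synthetic generator; defaults are the study design.

    The default taxonomy is deliberately desk-scale (10 phyla x 50 OTUs
    rather than a ~59,000-OTU chip); the full scale is reachable through
    the same fields.  ``effects`` maps an otu_id or any taxon name to the
    IN/OUT fold-change planted on matching OTUs (OTU-level entries win
    over taxon-level ones).
    """

    # taxonomy / probe library
    n_phyla: int = 10
    otus_per_phylum: int = 50
    n_archaeal_phyla: int = 1
    pairs_per_probe_set: int = 12
    n_spike_probes: int = 24
    # array design (one site, replicate pools per niche)
    n_in: int = 3
    n_out: int = 3
    # signal model
    presence_prob: float = 0.85
    effects: Mapping[str, float] = field(default_factory=dict)
    pm_signal_mean: float = 10000.0
    background_mean: float = 25.0
    mm_leak_fraction: float = 0.002
    spike_mean: float = 5000.0
    lognormal_sigma: float = 0.3
    crosshyb_rate: float = 0.05
    crosshyb_shared_fraction: float = 0.5
    array_scale_jitter: float = 0.1
    # fingerprint design (sites x replicate lanes per niche)
    n_sites: int = 4
    lanes_per_group: int = 4
    n_grid: int = 200
    n_bands: int = 40
    band_width: float = 0.012
    band_presence_prob: float = 0.7
    band_amp_sigma: float = 0.5
    site_effect_sigma: float = 0.3
    n_shifted_bands: int = 0
    shift_in_prob: float = 0.9
    shift_out_prob: float = 0.1
    profile_noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        rates = {
            "presence_prob": self.presence_prob,
            "crosshyb_rate": self.crosshyb_rate,
            "crosshyb_shared_fraction": self.crosshyb_shared_fraction,
            "mm_leak_fraction": self.mm_leak_fraction,
            "band_presence_prob": self.band_presence_prob,
            "shift_in_prob": self.shift_in_prob,
            "shift_out_prob": self.shift_out_prob,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        for name, value in self.effects.items():
            if value <= 0:
                raise ValueError(f"fold-change for {name!r} must be > 0, got {value}")
        if self.pairs_per_probe_set < 1:
            raise ValueError("pairs_per_probe_set must be >= 1")
        if min(self.n_in, self.n_out) < 1 or min(self.n_sites, self.lanes_per_group) < 1:
            raise ValueError("design sizes must be >= 1")
        if not 0 <= self.n_archaeal_phyla <= self.n_phyla:
            raise ValueError("n_archaeal_phyla must lie in [0, n_phyla]")
        if self.n_shifted_bands > self.n_bands:
            raise ValueError("n_shifted_bands cannot exceed n_bands")
        for name in ("lognormal_sigma", "array_scale_jitter", "background_mean",
                     "band_amp_sigma", "site_effect_sigma", "profile_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery checks."""

    presence: Optional[pd.DataFrame] = None  # otu x sample, bool
    fold_change: Optional[pd.Series] = None  # per otu (IN/OUT ratio)
    band_positions: Optional[pd.Series] = None  # per band
    band_group_prob: Optional[pd.DataFrame] = None  # band x group


# ---------------------------------------------------------------------------
# Taxonomy / library construction (deterministic given the config)
# ---------------------------------------------------------------------------


def _build_taxonomy(config: SimulationConfig) -> TaxonomyTable:
    rows: List[Tuple[str, ...]] = []
    ids: List[str] = []
    counter = 0
    opp = config.otus_per_phylum
    for p in range(config.n_phyla):
        archaeal = p >= config.n_phyla - config.n_archaeal_phyla
        domain = "Archaea" if archaeal else "Bacteria"
        phylum = f"Phylum{p:02d}"
        for j in range(opp):
            cls_ = f"{phylum}_c{(2 * j) // opp}"
            order = f"{cls_}_o0"
            fam = f"{phylum}_f{(4 * j) // opp}"
            genus = f"{phylum}_g{j // max(1, opp // 8)}"
            ids.append(f"otu{counter:05d}")
            rows.append((domain, phylum, cls_, order, fam, genus))
            counter += 1
    table = pd.DataFrame(rows, columns=list(RANKS), index=pd.Index(ids, name="otu_id"))
    return TaxonomyTable(table)


def _build_library(config: SimulationConfig, taxonomy: TaxonomyTable, rng: np.random.Generator) -> ProbeLibrary:
    pair_ids = [f"pr{k:02d}" for k in range(config.pairs_per_probe_set)]
    probe_sets = {
        otu: [ProbePair(pid, f"{otu}.{pid}.pm", f"{otu}.{pid}.mm") for pid in pair_ids]
        for otu in taxonomy.otu_ids
    }
    spikes = [f"spike{k:03d}" for k in range(config.n_spike_probes)]

    crosshyb: Dict[Tuple[str, str], frozenset] = {}
    if config.crosshyb_rate > 0:
        phyla = taxonomy.lineages["phylum"]
        otus = list(taxonomy.otu_ids)
        n_shared = max(1, int(round(config.crosshyb_shared_fraction * config.pairs_per_probe_set)))
        for a, b in zip(otus, otus[1:]):
            if phyla[a] != phyla[b]:
                continue
            if rng.random() < config.crosshyb_rate:
                shared = rng.choice(pair_ids, size=n_shared, replace=False)
                crosshyb[(a, b)] = frozenset(shared.tolist())
    return ProbeLibrary(probe_sets, spikes, crosshyb)


def _resolve_folds(config: SimulationConfig, taxonomy: TaxonomyTable) -> pd.Series:
    folds = pd.Series(1.0, index=taxonomy.otu_ids, name="fold_change")
    if not config.effects:
        return folds
    # taxon-level entries first, otu-level entries override
    for rank in RANKS:
        col = taxonomy.lineages[rank]
        for name, fold in config.effects.items():
            folds[col == name] = fold
    for name, fold in config.effects.items():
        if name in folds.index:
            folds[name] = fold
    return folds


# ---------------------------------------------------------------------------
# Array arm
# ---------------------------------------------------------------------------


def array_design(config: SimulationConfig) -> pd.DataFrame:
    samples = [f"In_{r + 1}" for r in range(config.n_in)] + [
        f"Out_{r + 1}" for r in range(config.n_out)
    ]
    groups = ["IN"] * config.n_in + ["OUT"] * config.n_out
    pools = list(range(1, config.n_in + 1)) + list(range(1, config.n_out + 1))
    return pd.DataFrame(
        {"group": groups, "site": "S1", "pool": pools},
        index=pd.Index(samples, name="sample_id"),
    )


def simulate_array(
    config: SimulationConfig,
) -> Tuple[ProbeLibrary, TaxonomyTable, ArrayExperiment, GroundTruth]:
    """Generate one spike-calibrated PM/MM array experiment.

    For a truly present OTU the PM intensity of each pair is
    ``background*exp(sigma*Z) + S*fold^g*exp(sigma*Z')`` with
    ``S = pm_signal_mean`` and ``g = 1`` for IN samples, and the MM
    intensity is its own background draw plus ``mm_leak_fraction`` of the
    PM target signal.  Absent OTUs see background only, except on pairs
    shared with a present cross-hybridising neighbour, which leak the
    neighbour's signal.  Finally every probe on an array is multiplied by
    a per-array scale factor ``exp(N(0, array_scale_jitter))``; the spike
    probes carry that factor and nothing else group-specific, which is
    what makes spike rescaling recover comparability across samples.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    taxonomy = _build_taxonomy(config)
    library = _build_library(config, taxonomy, rng)
    folds = _resolve_folds(config, taxonomy)
    design = array_design(config)
    samples = list(design.index)
    n_samp = len(samples)
    otus = list(taxonomy.otu_ids)
    n_otu = len(otus)

    presence = rng.random((n_otu, n_samp)) < config.presence_prob
    presence_df = pd.DataFrame(presence, index=pd.Index(otus, name="otu_id"), columns=samples)

    idx = library.probe_index()
    n_rows = len(idx)
    otu_pos = {otu: i for i, otu in enumerate(otus)}
    row_otu = idx["otu_id"].map(otu_pos).to_numpy()
    is_in = (design["group"] == "IN").to_numpy()

    sigma = config.lognormal_sigma
    # per-OTU, per-sample mean target signal (fold applied to IN samples)
    mean_sig = config.pm_signal_mean * np.where(
        is_in[None, :], folds.to_numpy()[:, None], 1.0
    )
    # per-pair lognormal draws around the OTU/sample mean, zeroed when absent
    sig = (
        mean_sig[row_otu]
        * np.exp(sigma * rng.standard_normal((n_rows, n_samp)))
        * presence[row_otu]
    )

    # cross-hybridising shared pairs leak the neighbour's target signal
    if library.crosshyb:
        row_of = {(o, p): i for i, (o, p) in enumerate(zip(idx["otu_id"], idx["pair_id"]))}
        bleed = np.zeros_like(sig)
        for (a, b), shared in library.crosshyb.items():
            for pid in sorted(shared):
                ra, rb = row_of[(a, pid)], row_of[(b, pid)]
                bleed[ra] += sig[rb]
                bleed[rb] += sig[ra]
        sig = sig + bleed

    bg = config.background_mean
    pm = bg * np.exp(sigma * rng.standard_normal((n_rows, n_samp))) + sig
    mm = bg * np.exp(sigma * rng.standard_normal((n_rows, n_samp))) + config.mm_leak_fraction * sig
    spikes = config.spike_mean * np.exp(
        sigma * rng.standard_normal((len(library.spike_probes), n_samp))
    )

    scale = np.exp(config.array_scale_jitter * rng.standard_normal(n_samp))
    matrix = np.vstack([pm, mm, spikes]) * scale[None, :]
    probe_ids = list(idx["pm"]) + list(idx["mm"]) + list(library.spike_probes)
    intensities = pd.DataFrame(matrix, index=pd.Index(probe_ids, name="probe_id"), columns=samples)

    experiment = ArrayExperiment(intensities, design, taxonomy.domains())
    truth = GroundTruth(presence=presence_df, fold_change=folds)
    return library, taxonomy, experiment, truth


# ---------------------------------------------------------------------------
# Fingerprint arm
# ---------------------------------------------------------------------------


def fingerprint_design(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for s in range(config.n_sites):
        site = f"S{s + 1}"
        for grp, tag in (("IN", "In"), ("OUT", "Out")):
            for r in range(config.lanes_per_group):
                rows.append((f"{site}_{tag}{r + 1}", grp, site, r + 1))
    df = pd.DataFrame(rows, columns=["sample_id", "group", "site", "pool"])
    return df.set_index("sample_id")


def simulate_fingerprints(config: SimulationConfig) -> Tuple[FingerprintSet, GroundTruth]:
    """Generate gel-fingerprint lanes as sums of Gaussian band profiles.

    Band positions, amplitudes and (site, band) amplitude multipliers are
    drawn once; each lane then includes band ``b`` with its group's
    presence probability.  ``n_shifted_bands`` bands get niche-specific
    probabilities (``shift_in_prob`` vs ``shift_out_prob``) — the planted
    community difference.  Nonnegative half-normal noise is added on top.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    design = fingerprint_design(config)
    samples = list(design.index)
    grid = np.linspace(0.0, 1.0, config.n_grid)

    positions = np.sort(rng.uniform(0.05, 0.95, config.n_bands))
    amps = np.exp(config.band_amp_sigma * rng.standard_normal(config.n_bands))
    site_mult = np.exp(
        config.site_effect_sigma * rng.standard_normal((config.n_sites, config.n_bands))
    )
    shifted = rng.choice(config.n_bands, size=config.n_shifted_bands, replace=False)

    prob = pd.DataFrame(
        {"IN": config.band_presence_prob, "OUT": config.band_presence_prob},
        index=pd.RangeIndex(config.n_bands, name="band"),
        dtype=float,
    )
    prob.iloc[shifted, prob.columns.get_loc("IN")] = config.shift_in_prob
    prob.iloc[shifted, prob.columns.get_loc("OUT")] = config.shift_out_prob

    profiles = np.exp(-((grid[None, :] - positions[:, None]) ** 2) / (2 * config.band_width**2))

    lanes = np.zeros((len(samples), config.n_grid))
    site_of = {f"S{s + 1}": s for s in range(config.n_sites)}
    for i, sample in enumerate(samples):
        grp = design.loc[sample, "group"]
        s = site_of[design.loc[sample, "site"]]
        present = rng.random(config.n_bands) < prob[grp].to_numpy()
        weights = present * amps * site_mult[s]
        lanes[i] = weights @ profiles
    lanes += np.abs(rng.normal(0.0, config.profile_noise, lanes.shape))

    lane_df = pd.DataFrame(lanes.T, index=pd.Index(grid, name="position"), columns=samples)
    truth = GroundTruth(
        band_positions=pd.Series(positions, name="position").rename_axis("band"),
        band_group_prob=prob,
    )
    return FingerprintSet(lane_df, design), truth


# ---------------------------------------------------------------------------
# Dataset writers (all core formats + ground truth TSV)
# ---------------------------------------------------------------------------


def write_array_dataset(out_dir, library, taxonomy, experiment, truth) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bio.write_probe_map(library, out / "probe_map.tsv", out / "crosshyb.tsv")
    bio.write_taxonomy(taxonomy, out / "taxonomy.tsv")
    bio.write_design(experiment.design, out / "design.tsv")
    bio.write_intensities(experiment, out / "intensities.tsv")
    if truth.presence is not None:
        truth.presence.rename_axis("otu_id").to_csv(out / "truth_presence.tsv", sep="\t")
    if truth.fold_change is not None:
        truth.fold_change.rename_axis("otu_id").to_csv(out / "truth_fold_change.tsv", sep="\t")


def write_fingerprint_dataset(out_dir, fingerprints, truth) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bio.write_design(fingerprints.design, out / "design.tsv")
    bio.write_fingerprints(fingerprints, out / "fingerprints.tsv")
    if truth.band_group_prob is not None:
        tb = truth.band_group_prob.copy()
        tb.insert(0, "position", truth.band_positions)
        tb.to_csv(out / "truth_bands.tsv", sep="\t")
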
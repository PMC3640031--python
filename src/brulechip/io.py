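"""Readers and writers for the package's plain tab-separated formats.

Every format is TSV with a mandatory header row:

* probe map     — probe_id, otu_id, role (PM/MM), pair_id; spike probes
  carry the reserved otu_id ``SPIKE``.
* crosshyb map  — otu_a, otu_b, pair_id (one shared pair per row).
* taxonomy      — otu_id, lineage (semicolon-joined ``k__;p__;...;g__``).
* design        — sample_id, group, site, pool.
* intensities   — probe_id then one column per sample.
* fingerprints  — position then one column per sample (lane).
* calls         — the long-form call table of :class:`OtuCallTable`.

Readers enforce the type invariants from :mod:`brulechip.model` and
raise :class:`~brulechip.model.FormatError` on violations; writers emit
files their readers accept (round-trip identity).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Tuple, Union

import pandas as pd

from .model import (
    ArrayExperiment,
    FingerprintSet,
    FormatError,
    OtuCallTable,
    ProbeLibrary,
    ProbePair,
    TaxonomyTable,
    RANKS,
    format_lineage,
    parse_lineage,
    validate_design,
)

PathLike = Union[str, Path]

SPIKE_LABEL = "SPIKE"


def _read_tsv(path: PathLike, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, **kw)
    except pd.errors.EmptyDataError as exc:  # pragma: no cover - defensive
        raise FormatError(f"{path}: empty file") from exc


def _require_columns(df: pd.DataFrame, cols: List[str], path: PathLike) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")


# ---------------------------------------------------------------------------
# Probe map
# ---------------------------------------------------------------------------


def read_probe_map(path: PathLike, crosshyb_path: Optional[PathLike] = None) -> ProbeLibrary:
    """Read a probe map (and optional cross-hybridisation table)."""
    df = _read_tsv(path)
    _require_columns(df, ["probe_id", "otu_id", "role", "pair_id"], path)
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise FormatError(f"{path}: duplicate probe_id {dup!r}")
    bad_roles = set(df["role"]) - {"PM", "MM"}
    if bad_roles:
        raise FormatError(f"{path}: unknown probe roles {sorted(bad_roles)}")

    spikes = df[df["otu_id"] == SPIKE_LABEL]
    otus = df[df["otu_id"] != SPIKE_LABEL]

    probe_sets: Dict[str, List[ProbePair]] = {}
    for (otu, pair), grp in otus.groupby(["otu_id", "pair_id"], sort=False):
        roles = dict(zip(grp["role"], grp["probe_id"]))
        if set(roles) != {"PM", "MM"}:
            raise FormatError(f"{path}: pair {pair!r} of {otu!r} must have exactly one PM and one MM row")
        probe_sets.setdefault(otu, []).append(ProbePair(pair, roles["PM"], roles["MM"]))

    crosshyb: Dict[Tuple[str, str], FrozenSet[str]] = {}
    if crosshyb_path is not None:
        cdf = _read_tsv(crosshyb_path)
        _require_columns(cdf, ["otu_a", "otu_b", "pair_id"], crosshyb_path)
        acc: Dict[Tuple[str, str], set] = {}
        for a, b, pid in cdf.itertuples(index=False):
            if a == b:
                raise FormatError(f"{crosshyb_path}: crosshyb pair references one OTU twice ({a!r})")
            key = (a, b) if a < b else (b, a)
            acc.setdefault(key, set()).add(pid)
        crosshyb = {k: frozenset(v) for k, v in acc.items()}

    return ProbeLibrary(probe_sets, list(spikes["probe_id"]), crosshyb)


def write_probe_map(
    library: ProbeLibrary, path: PathLike, crosshyb_path: Optional[PathLike] = None
) -> None:
    rows = []
    for otu, pairs in library.probe_sets.items():
        for p in pairs:
            rows.append((p.pm_probe_id, otu, "PM", p.pair_id))
            rows.append((p.mm_probe_id, otu, "MM", p.pair_id))
    for pid in library.spike_probes:
        rows.append((pid, SPIKE_LABEL, "PM", pid))
    pd.DataFrame(rows, columns=["probe_id", "otu_id", "role", "pair_id"]).to_csv(
        path, sep="\t", index=False
    )
    if crosshyb_path is not None:
        crows = [
            (a, b, pid)
            for (a, b), shared in sorted(library.crosshyb.items())
            for pid in sorted(shared)
        ]
        pd.DataFrame(crows, columns=["otu_a", "otu_b", "pair_id"]).to_csv(
            crosshyb_path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


def read_taxonomy(path: PathLike) -> TaxonomyTable:
    df = _read_tsv(path, keep_default_na=False)
    _require_columns(df, ["otu_id", "lineage"], path)
    slots = [parse_lineage(t) for t in df["lineage"]]
    table = pd.DataFrame(slots, columns=list(RANKS), index=pd.Index(df["otu_id"], name="otu_id"))
    return TaxonomyTable(table)


def write_taxonomy(taxonomy: TaxonomyTable, path: PathLike) -> None:
    out = pd.DataFrame(
        {
            "otu_id": taxonomy.lineages.index,
            "lineage": [format_lineage(row) for row in taxonomy.lineages.itertuples(index=False)],
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------


def read_design(path: PathLike) -> pd.DataFrame:
    df = _read_tsv(path, keep_default_na=False)
    _require_columns(df, ["sample_id", "group", "site", "pool"], path)
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample_id")
    out = df.set_index("sample_id")
    try:  # pool ids are usually numeric; group/site stay as labels
        out["pool"] = pd.to_numeric(out["pool"])
    except (ValueError, TypeError):
        pass
    return validate_design(out)


def write_design(design: pd.DataFrame, path: PathLike) -> None:
    design.rename_axis("sample_id").reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Intensity matrix / fingerprints
# ---------------------------------------------------------------------------


def read_intensities(
    path: PathLike,
    design: pd.DataFrame,
    library: Optional[ProbeLibrary] = None,
    taxonomy: Optional[TaxonomyTable] = None,
) -> ArrayExperiment:
    """Read a probe × sample matrix and join the sample design.

    When ``taxonomy`` is given, per-OTU domain labels (bacteria/archaea)
    are attached for the calling stage.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "probe_id":
        raise FormatError(f"{path}: first column must be 'probe_id', got {df.columns[0]!r}")
    matrix = df.set_index("probe_id").astype(float)
    domain = taxonomy.domains() if taxonomy is not None else None
    exp = ArrayExperiment(matrix, design, domain)
    if library is not None:
        exp.check_library(library)
    return exp


def write_intensities(experiment: ArrayExperiment, path: PathLike) -> None:
    experiment.intensities.rename_axis("probe_id").to_csv(path, sep="\t")


def read_fingerprints(path: PathLike, design: pd.DataFrame) -> FingerprintSet:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "position":
        raise FormatError(f"{path}: first column must be 'position', got {df.columns[0]!r}")
    lanes = df.set_index("position").astype(float)
    return FingerprintSet(lanes, design)


def write_fingerprints(fingerprints: FingerprintSet, path: PathLike) -> None:
    fingerprints.lanes.rename_axis("position").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Call tables
# ---------------------------------------------------------------------------


def read_calls(path: PathLike) -> OtuCallTable:
    df = pd.read_csv(path, sep="\t")
    if "present" not in df.columns:
        raise FormatError(f"{path}: not a call table (no 'present' column)")
    df["present"] = df["present"].astype(bool)
    return OtuCallTable(df)


def write_calls(calls: OtuCallTable, path: PathLike) -> None:
    calls.calls.to_csv(path, sep="\t", index=False)
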
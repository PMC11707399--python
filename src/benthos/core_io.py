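"""Data model, file readers/writers and pre-analysis standardization.

The survey design this package targets is a bottom-trawl megabenthos survey:
catches are standardized to densities by the swept-area method (net width x
tow distance), severely damaged specimens have their wet mass imputed from
conspecifics, and both biotic and environmental tables are log(x+1)
transformed before analysis.

Containers are thin dataclasses around :class:`pandas.DataFrame` so that the
whole pipeline speaks sites x species (or sites x parameters) matrices with
explicit registries and validated invariants.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import networkx as nx
from skbio import TreeNode

# ---------------------------------------------------------------------------
# registries and constants
# ---------------------------------------------------------------------------

#: sample-table kinds and their units
KIND_ABUNDANCE = "abundance"  # ind km^-2
KIND_BIOMASS = "biomass"      # kg km^-2
KIND_COUNT = "count"          # raw individuals
SAMPLE_KINDS = (KIND_ABUNDANCE, KIND_BIOMASS, KIND_COUNT)

#: the environmental parameter registry (bottom seawater)
ENV_PARAMS = (
    "Tem",   # temperature, degC
    "Sa",    # salinity (PSU, dimensionless)
    "pH",
    "Tu",    # turbidity
    "Depth",  # m
    "Chl",   # chlorophyll a
    "NO3", "NO2", "NH4",  # nitrogen species
    "PO4",   # phosphate
    "SiO3",  # silicate
    "DIN",   # dissolved inorganic nitrogen = NO3 + NH4 + NO2
    "N/P", "Si/N", "Si/P",  # stoichiometric ratios
)

#: survey cruises: spring low-flow, summer low-flow, artificial flood
CRUISES = ("IA", "IB", "IC")

M2_PER_KM2 = 1.0e6
G_PER_KG = 1.0e3


class BenthosError(ValueError):
    """Raised for invalid inputs anywhere in the pipeline."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def _check_registry(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dups = index[index.duplicated()].unique().tolist()
        raise BenthosError(f"duplicate {what} identifiers: {dups}")


@dataclass
class SampleTable:
    """Sites x species matrix of non-negative densities (or counts)."""

    data: pd.DataFrame
    kind: str = KIND_ABUNDANCE

    def __post_init__(self) -> None:
        if self.kind not in SAMPLE_KINDS:
            raise BenthosError(f"unknown sample kind {self.kind!r}")
        self.data = self.data.astype(float)
        _check_registry(self.data.index, "site")
        _check_registry(self.data.columns, "species")
        vals = self.data.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise BenthosError("sample table contains non-finite values")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise BenthosError(
                f"negative value at site {self.data.index[i]!r}, "
                f"species {self.data.columns[j]!r}"
            )

    @property
    def sites(self) -> list[str]:
        return list(self.data.index)

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_sites(self, sites) -> "SampleTable":
        return SampleTable(self.data.loc[list(sites)].copy(), self.kind)


@dataclass
class SiteMetadata:
    """Per-site registry: position, distance to the river mouth, labels."""

    data: pd.DataFrame  # index = site id

    REQUIRED = ("longitude", "latitude", "distance_to_estuary", "cruise", "group", "depth")

    def __post_init__(self) -> None:
        _check_registry(self.data.index, "site")
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise BenthosError(f"metadata missing columns: {missing}")
        if (self.data["distance_to_estuary"].astype(float) < 0).any():
            raise BenthosError("distance_to_estuary must be >= 0")
        bad = set(self.data["cruise"]) - set(CRUISES)
        if bad:
            raise BenthosError(f"unknown cruise labels: {sorted(bad)}")

    @property
    def sites(self) -> list[str]:
        return list(self.data.index)


@dataclass
class EnvironmentTable:
    """Sites x environmental-parameter matrix."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _check_registry(self.data.index, "site")
        _check_registry(self.data.columns, "parameter")

    @property
    def sites(self) -> list[str]:
        return list(self.data.index)

    @property
    def parameters(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class TrawlRecord:
    """One species' catch in one tow: counts plus per-individual wet masses.

    ``masses_g`` holds one entry per weighed individual; ``damaged`` flags
    individuals with severe body loss whose mass is unusable (NaN allowed
    there until imputation).
    """

    site: str
    species: str
    count: int
    width_m: float
    distance_m: float
    masses_g: list = field(default_factory=list)
    damaged: list = field(default_factory=list)
    tow_id: str = "T1"

    def __post_init__(self) -> None:
        if not self.damaged:
            self.damaged = [False] * len(self.masses_g)
        if len(self.damaged) != len(self.masses_g):
            raise BenthosError("damaged flags must match masses")
        if self.count < sum(bool(d) for d in self.damaged):
            raise BenthosError("count smaller than number of damaged individuals")


@dataclass
class SyntheticDataset:
    """Bundle produced by the scenario generator (see :mod:`benthos.synthetic`)."""

    abundance: SampleTable
    biomass: SampleTable
    environment: EnvironmentTable
    metadata: SiteMetadata
    tree: TreeNode
    true_groups: pd.Series
    niche: pd.DataFrame


# ---------------------------------------------------------------------------
# trawl standardization and damage imputation
# ---------------------------------------------------------------------------

def swept_area_km2(width_m: float, distance_m: float) -> float:
    """Swept area of one tow in km^2 (width x distance)."""
    return width_m * distance_m / M2_PER_KM2


def damage_report(records) -> dict:
    """Occurrence statistics of severely damaged specimens.

    Returns counts of damaged vs total individuals and the damaged occurrence
    rate in percent, the quantity survey reports quote when justifying mean
    imputation.
    """
    n_damaged = sum(sum(bool(d) for d in r.damaged) for r in records)
    n_total = sum(int(r.count) for r in records)
    rate = 100.0 * n_damaged / n_total if n_total else math.nan
    return {
        "n_damaged": n_damaged,
        "n_individuals": n_total,
        "damaged_rate_percent": rate,
    }


def impute_damaged_biomass(records) -> tuple[list, dict]:
    """Replace damaged individuals' masses by the conspecific undamaged mean.

    Species represented only by damaged individuals cannot be imputed: their
    records are returned unchanged and listed under ``"unimputable"`` so the
    biomass standardization can exclude them with full disclosure.
    """
    undamaged: dict[str, list[float]] = {}
    for r in records:
        pool = undamaged.setdefault(r.species, [])
        pool.extend(m for m, d in zip(r.masses_g, r.damaged) if not d)
    out = []
    imputed: dict[str, float] = {}
    unimputable: list[str] = []
    for r in records:
        if not any(r.damaged):
            out.append(r)
            continue
        pool = undamaged.get(r.species, [])
        if not pool:
            if r.species not in unimputable:
                unimputable.append(r.species)
            out.append(r)
            continue
        mean_mass = float(np.mean(pool))
        imputed[r.species] = mean_mass
        masses = [mean_mass if d else m for m, d in zip(r.masses_g, r.damaged)]
        out.append(replace(r, masses_g=masses, damaged=[False] * len(masses)))
    report = {"imputed_mean_mass_g": imputed, "unimputable": unimputable}
    report.update(damage_report(records))
    return out, report


def standardize_trawl(records) -> tuple[SampleTable, SampleTable, dict]:
    """Swept-area standardization of trawl catches.

    Abundance(site, sp) = sum of counts / total swept area of the site's tows
    (ratio of sums, so repeated tows pool without bias); biomass analogous
    from summed wet masses. Records with non-positive tow geometry are
    rejected into the report; species whose masses are still unusable
    (damaged, not imputed) are excluded from the biomass table only.
    """
    rejected = []
    valid = []
    for r in records:
        if r.width_m <= 0 or r.distance_m <= 0:
            rejected.append(
                {"site": r.site, "species": r.species, "tow": r.tow_id,
                 "reason": f"non-positive tow geometry (width={r.width_m}, distance={r.distance_m})"}
            )
        else:
            valid.append(r)
    if not valid:
        raise BenthosError("no valid trawl records")

    # swept area per site = sum over distinct tows (a tow may carry many species)
    tow_area: dict[tuple, float] = {}
    for r in valid:
        key = (r.site, r.tow_id)
        area = swept_area_km2(r.width_m, r.distance_m)
        if key in tow_area and not math.isclose(tow_area[key], area):
            raise BenthosError(f"inconsistent geometry for tow {key}")
        tow_area[key] = area
    site_area: dict[str, float] = {}
    for (site, _), area in tow_area.items():
        site_area[site] = site_area.get(site, 0.0) + area

    sites = sorted(site_area)
    species = sorted({r.species for r in valid})
    counts = pd.DataFrame(0.0, index=sites, columns=species)
    masses = pd.DataFrame(0.0, index=sites, columns=species)
    mass_excluded: set[str] = set()
    for r in valid:
        counts.loc[r.site, r.species] += r.count
        if r.masses_g:
            total = float(np.nansum(r.masses_g))
            if any(not np.isfinite(m) for m in r.masses_g):
                mass_excluded.add(r.species)
            masses.loc[r.site, r.species] += total
    areas = pd.Series(site_area)[sites]
    abundance = counts.div(areas, axis=0)
    biomass = masses.div(areas, axis=0) / G_PER_KG
    biomass.loc[:, sorted(mass_excluded)] = 0.0

    report = {
        "swept_area_km2": {s: site_area[s] for s in sites},
        "rejected_records": rejected,
        "biomass_excluded_species": sorted(mass_excluded),
    }
    report.update(damage_report(valid))
    return (
        SampleTable(abundance, KIND_ABUNDANCE),
        SampleTable(biomass, KIND_BIOMASS),
        report,
    )


# ---------------------------------------------------------------------------
# transforms and consistency checks
# ---------------------------------------------------------------------------

def log_transform(table, base: float = 10.0):
    """log_base(x + 1), the standard variance-stabilizing transform here.

    Accepts a SampleTable, EnvironmentTable or bare DataFrame and returns the
    same type; negative input raises an error naming the offending cell.
    """
    if isinstance(table, SampleTable):
        return SampleTable(log_transform(table.data, base), table.kind)
    if isinstance(table, EnvironmentTable):
        return EnvironmentTable(log_transform(table.data, base))
    df = table.astype(float)
    vals = df.to_numpy()
    if (vals < 0).any():
        i, j = np.argwhere(vals < 0)[0]
        raise BenthosError(
            f"cannot log-transform negative value at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    return pd.DataFrame(np.log1p(vals) / math.log(base), index=df.index, columns=df.columns)


def check_din_consistency(env: EnvironmentTable, tol: float = 1e-9) -> list[str]:
    """Sites where DIN != NO3 + NH4 + NO2 (within tolerance)."""
    df = env.data
    needed = {"DIN", "NO3", "NH4", "NO2"}
    if not needed.issubset(df.columns):
        return []
    resid = (df["DIN"] - (df["NO3"] + df["NH4"] + df["NO2"])).abs()
    return list(df.index[resid > tol])


def great_circle_km(lon1, lat1, lon2, lat2) -> float:
    """Haversine distance in km between two decimal-degree points."""
    r = 6371.0088
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * r * math.asin(math.sqrt(a))


def reconcile_tree(table: SampleTable, tree: TreeNode) -> dict:
    """Species coverage of the phylogeny over a sample table's registry."""
    tips = {t.name for t in tree.tips()}
    species = list(table.species)
    covered = [s for s in species if s in tips]
    missing = [s for s in species if s not in tips]
    return {
        "covered": covered,
        "missing_from_tree": missing,
        "coverage_fraction": len(covered) / len(species) if species else math.nan,
    }


# ---------------------------------------------------------------------------
# readers / writers (delimited text, Newick, GraphML, JSON)
# ---------------------------------------------------------------------------

def _read_matrix(path_or_buf, what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path_or_buf, sep=None, engine="python", index_col=0)
    except Exception as exc:  # pandas errors carry the line number
        raise BenthosError(f"cannot parse {what} table: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise BenthosError(
                f"non-numeric cell in {what} table at row {row!r}, column {col!r}"
            )
    return df.astype(float)


def read_sample_table(path, kind: str = KIND_ABUNDANCE) -> SampleTable:
    return SampleTable(_read_matrix(path, "sample"), kind)


def write_sample_table(table: SampleTable, path, sep: str = "\t") -> None:
    table.data.to_csv(path, sep=sep)


def read_environment_table(path) -> EnvironmentTable:
    return EnvironmentTable(_read_matrix(path, "environment"))


def write_environment_table(env: EnvironmentTable, path, sep: str = "\t") -> None:
    env.data.to_csv(path, sep=sep)


def read_metadata(path) -> SiteMetadata:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str)
    return SiteMetadata(df)


def write_metadata(meta: SiteMetadata, path, sep: str = "\t") -> None:
    meta.data.to_csv(path, sep=sep)


def read_tree(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def tree_from_newick(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick), format="newick")


def read_network(path) -> nx.Graph:
    return nx.read_graphml(str(path))


def write_network(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, str(path))


def write_edge_list(graph: nx.Graph, path, sep: str = "\t") -> None:
    rows = [
        {"source": u, "target": v, **d}
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Series,)):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")
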
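"""Core data containers, readers, validation, filtering and transforms.

The pipeline starts from four processed tables:

* an abundance table of molecular OTU (MOTU) read counts per soil sample,
* sample metadata (site, bedrock, cushion/bare location, plant genetic
  cluster, elevation, planar coordinates),
* soil chemistry (total N, total C, gravimetric water, nitrate, ammonium, pH),
* a binary AFLP fingerprint matrix for the cushion plant individuals.

Everything downstream consumes the validated containers defined here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Valid category levels for the metadata factors.
BEDROCKS = ("granite", "limestone", "quartzite")
LOCATIONS = ("cushion", "bare")
CLUSTERS = ("exscapa", "longiscapa", "ambiguous")

#: Chemistry variables, in canonical column order.
CHEM_VARS = ("total_n", "total_c", "water", "no3", "nh4", "ph")

#: Letter codes used to label habitats (cluster, bedrock, location).
_CLUSTER_LETTER = {"exscapa": "x", "longiscapa": "l"}
_BEDROCK_LETTER = {"granite": "G", "limestone": "C"}
_LOCATION_LETTER = {"cushion": "c", "bare": "b"}

#: The six habitats crossing plant cluster, bedrock and location, after
#: quartzite sites and ambiguous plants are excluded.
HABITATS = ("xGb", "xGc", "xCb", "xCc", "lCb", "lCc")
CUSHION_HABITATS = ("xGc", "xCc", "lCc")
BARE_HABITATS = ("xGb", "xCb", "lCb")

_ROW_SUM_TOL = 1e-9


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class AbundanceTable:
    """Samples x MOTUs matrix of read counts or proportions.

    ``mode`` records the transform state: raw ``counts``, ``relative``
    (rows sum to one) or ``hellinger`` (rows of square roots of relative
    abundances, so squared rows sum to one).
    """

    data: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative", "hellinger"):
            raise ValidationError(f"unknown abundance mode {self.mode!r}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample_id: {dupes}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate motu_id: {dupes}")
        values = self.data.to_numpy(dtype=float)
        if (values < 0).any():
            bad = self.data.index[(values < 0).any(axis=1)].tolist()
            raise ValidationError(f"negative count in samples {bad}")
        if self.mode == "relative":
            sums = values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=_ROW_SUM_TOL, rtol=0):
                raise ValidationError("relative rows must sum to 1")
        elif self.mode == "hellinger":
            sums = (values**2).sum(axis=1)
            if not np.allclose(sums, 1.0, atol=_ROW_SUM_TOL, rtol=0):
                raise ValidationError("hellinger rows must have unit square-sum")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def motu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceTable":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples absent from table: {missing}")
        return AbundanceTable(self.data.loc[ids].copy(), mode=self.mode)


@dataclass
class SampleMetadata:
    """Per-sample design factors; one row per sample_id (the index)."""

    data: pd.DataFrame

    _REQUIRED = ("site", "bedrock", "location", "cluster", "elevation", "x", "y")

    def __post_init__(self) -> None:
        for col in self._REQUIRED:
            if col not in self.data.columns:
                raise FormatError(f"metadata missing column {col!r}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample_id: {dupes}")
        for col, levels in (("bedrock", BEDROCKS), ("location", LOCATIONS), ("cluster", CLUSTERS)):
            bad = set(self.data[col]) - set(levels)
            if bad:
                raise ValidationError(f"unknown {col} value(s) {sorted(bad)}")
        # a site hosts a single genetic cluster unless flagged ambiguous
        per_site = self.data.groupby("site")["cluster"].nunique()
        mixed = per_site[per_site > 1].index
        for site in mixed:
            clusters = set(self.data.loc[self.data["site"] == site, "cluster"])
            if "ambiguous" not in clusters:
                raise ValidationError(
                    f"site {site!r} mixes clusters {sorted(clusters)} without ambiguous flag"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def require_samples(self, sample_ids: Iterable[str]) -> None:
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")


@dataclass
class SoilChemistry:
    """Soil chemistry table: six variables per sample (index = sample_id)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in CHEM_VARS:
            if col not in self.data.columns:
                raise FormatError(f"chemistry missing column {col!r}")
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate sample_id in chemistry table")
        conc = self.data[["total_n", "total_c", "water", "no3", "nh4"]].to_numpy(float)
        if (conc < 0).any():
            raise ValidationError("negative concentration in chemistry table")
        ph = self.data["ph"].to_numpy(float)
        if ((ph <= 0) | (ph >= 14)).any():
            raise ValidationError("pH outside (0, 14)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class AFLPMatrix:
    """Binary AFLP fingerprints: individuals x loci, entries in {0, 1}."""

    data: pd.DataFrame
    #: optional map from plant individual_id to the cushion sample it grows in
    sample_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValidationError("AFLP matrix entries must be 0 or 1")
        zero = self.data.index[values.sum(axis=1) == 0].tolist()
        if zero:
            raise ValidationError(f"all-zero AFLP fingerprint for {zero}")
        unknown = [i for i in self.sample_map if i not in self.data.index]
        if unknown:
            raise ValidationError(f"sample_map refers to unknown individuals {unknown}")

    @property
    def individual_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_abundance(path: str | Path) -> AbundanceTable:
    """Read a TSV abundance table (first column ``sample_id``, MOTU columns)."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "sample_id":
        raise FormatError(f"{path}: first column must be 'sample_id'")
    df = df.set_index("sample_id")
    values = df.to_numpy()
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric abundance cell ({exc})") from exc
    if (values < 0).any():
        raise ValidationError(f"{path}: negative count")
    return AbundanceTable(df.astype(float), mode="counts")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing column 'sample_id'")
    return SampleMetadata(df.set_index("sample_id"))


def read_chemistry(path: str | Path) -> SoilChemistry:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing column 'sample_id'")
    return SoilChemistry(df.set_index("sample_id"))


def read_aflp(path: str | Path, map_path: str | Path | None = None) -> AFLPMatrix:
    df = pd.read_csv(path)
    if df.columns[0] != "individual_id":
        raise FormatError(f"{path}: first column must be 'individual_id'")
    df = df.set_index("individual_id")
    sample_map: dict[str, str] = {}
    if map_path is not None:
        mp = pd.read_csv(map_path)
        for col in ("individual_id", "sample_id"):
            if col not in mp.columns:
                raise FormatError(f"{map_path}: missing column {col!r}")
        sample_map = dict(zip(mp["individual_id"], mp["sample_id"]))
    return AFLPMatrix(df.astype(int), sample_map=sample_map)


def read_tables(
    abundance_path: str | Path,
    metadata_path: str | Path,
    chemistry_path: str | Path,
    aflp_path: str | Path,
    aflp_map_path: str | Path | None = None,
) -> tuple[AbundanceTable, SampleMetadata, SoilChemistry, AFLPMatrix]:
    """Read and cross-validate the four input tables.

    Every sample in the abundance table must have a metadata row; violations
    raise a :class:`ValidationError` naming the offending samples.
    """
    table = read_abundance(abundance_path)
    meta = read_metadata(metadata_path)
    chem = read_chemistry(chemistry_path)
    aflp = read_aflp(aflp_path, aflp_map_path)
    meta.require_samples(table.sample_ids)
    return table, meta, chem, aflp


def write_abundance(table: AbundanceTable, path: str | Path) -> None:
    df = table.data.copy()
    if table.mode == "counts":
        df = df.astype(int)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    df = meta.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, float_format="%.17g")


def write_chemistry(chem: SoilChemistry, path: str | Path) -> None:
    df = chem.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, float_format="%.17g")


def write_aflp(aflp: AFLPMatrix, path: str | Path, map_path: str | Path | None = None) -> None:
    df = aflp.data.copy()
    df.index.name = "individual_id"
    df.to_csv(path)
    if map_path is not None:
        pd.DataFrame(
            {"individual_id": list(aflp.sample_map), "sample_id": list(aflp.sample_map.values())}
        ).to_csv(map_path, index=False)


# ---------------------------------------------------------------------------
# filtering and transforms
# ---------------------------------------------------------------------------


def filter_table(
    table: AbundanceTable,
    min_sample_reads: int = 900,
    min_motu_reads: int = 10,
    keep_motus: Iterable[str] | None = None,
) -> AbundanceTable:
    """Drop shallow samples, then rare MOTUs, from a count table.

    Samples whose total reads fall below ``min_sample_reads`` are removed
    first; MOTU totals are then recomputed and MOTUs below ``min_motu_reads``
    (or absent from ``keep_motus`` when given) are discarded.  ``keep_motus``
    stands in for an external taxonomy screen (e.g. restricting to MOTUs
    assigned to the fungal kingdom).
    """
    if table.mode != "counts":
        raise ValidationError("filter_table requires a counts-mode table")
    df = table.data
    sample_totals = df.sum(axis=1)
    kept_samples = sample_totals >= min_sample_reads
    n_dropped_samples = int((~kept_samples).sum())
    df = df.loc[kept_samples]
    if df.empty:
        raise ValidationError("all samples filtered")
    if keep_motus is not None:
        df = df.loc[:, [m for m in df.columns if m in set(keep_motus)]]
    motu_totals = df.sum(axis=0)
    kept_motus = motu_totals >= min_motu_reads
    n_dropped_motus = int((~kept_motus).sum())
    df = df.loc[:, kept_motus]
    if df.shape[1] == 0:
        raise ValidationError("all MOTUs filtered")
    logger.info(
        "filter_table: removed %d samples (< %d reads) and %d MOTUs (< %d reads)",
        n_dropped_samples,
        min_sample_reads,
        n_dropped_motus,
        min_motu_reads,
    )
    return AbundanceTable(df.copy(), mode="counts")


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Divide each sample row by its total; rows then sum to one."""
    if table.mode == "relative":
        return table
    if table.mode != "counts":
        raise ValidationError("to_relative expects a counts table")
    values = table.values
    totals = values.sum(axis=1)
    zero = np.asarray(table.sample_ids)[totals == 0].tolist()
    if zero:
        raise ValidationError(f"all-zero sample row(s): {zero}")
    rel = values / totals[:, None]
    return AbundanceTable(
        pd.DataFrame(rel, index=table.data.index, columns=table.data.columns),
        mode="relative",
    )


def hellinger(table: AbundanceTable) -> AbundanceTable:
    """Square roots of relative abundances; damps dominant MOTUs."""
    rel = to_relative(table) if table.mode == "counts" else table
    if rel.mode != "relative":
        raise ValidationError("hellinger expects counts or relative input")
    values = np.sqrt(rel.values)
    return AbundanceTable(
        pd.DataFrame(values, index=rel.data.index, columns=rel.data.columns),
        mode="hellinger",
    )


# ---------------------------------------------------------------------------
# habitats and coordinates
# ---------------------------------------------------------------------------


def habitat_code(cluster: str, bedrock: str, location: str) -> str:
    """Three-letter habitat code, e.g. ('exscapa','granite','cushion') -> 'xGc'."""
    try:
        return _CLUSTER_LETTER[cluster] + _BEDROCK_LETTER[bedrock] + _LOCATION_LETTER[location]
    except KeyError as exc:
        raise ValidationError(f"no habitat code for {(cluster, bedrock, location)}") from exc


def assign_habitats(
    meta: SampleMetadata,
    exclude_quartzite: bool = True,
    exclude_ambiguous: bool = True,
) -> dict[str, str]:
    """Map each sample to one of the six habitat codes.

    Quartzite sites (atypical chemistry) and samples from sites whose plants
    could not be assigned to a genetic cluster are excluded by default, so
    the remaining samples fall into the six-habitat cross of cluster
    (exscapa/longiscapa), bedrock (granite/limestone) and location
    (cushion/bare).
    """
    out: dict[str, str] = {}
    for sample_id, row in meta.data.iterrows():
        if exclude_quartzite and row["bedrock"] == "quartzite":
            continue
        if row["cluster"] == "ambiguous":
            if exclude_ambiguous:
                continue
            raise ValidationError(
                f"sample {sample_id!r} has ambiguous cluster; set exclude_ambiguous"
            )
        if row["bedrock"] == "quartzite":
            raise ValidationError(
                f"sample {sample_id!r} on quartzite has no habitat code; set exclude_quartzite"
            )
        out[str(sample_id)] = habitat_code(row["cluster"], row["bedrock"], row["location"])
    return out


_EARTH_RADIUS_M = 6_371_000.0


def lonlat_to_planar(
    lon: np.ndarray, lat: np.ndarray, ref_lon: float | None = None, ref_lat: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Project lon/lat (degrees) to local planar metres.

    Uses an equirectangular projection about the reference point (default:
    the centroid).  Adequate for extents of a few tens of kilometres.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if ref_lon is None:
        ref_lon = float(lon.mean())
    if ref_lat is None:
        ref_lat = float(lat.mean())
    x = np.radians(lon - ref_lon) * math.cos(math.radians(ref_lat)) * _EARTH_RADIUS_M
    y = np.radians(lat - ref_lat) * _EARTH_RADIUS_M
    return x, y
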
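"""Pairwise distance layers and per-sample diversity.

Four layers feed the dissimilarity models: Bray-Curtis community
dissimilarity (on relative or Hellinger-transformed abundances), Jaccard
distance between AFLP fingerprints of the host plants, Euclidean distance on
standardized soil chemistry, and planar geographic distance.  Cognate
cushion/bare contrasts within sites quantify soil engineering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core_data import (
    AFLPMatrix,
    AbundanceTable,
    CHEM_VARS,
    SampleMetadata,
    SoilChemistry,
)
from .errors import ValidationError

_SYM_TOL = 1e-12


@dataclass
class DistanceMatrix:
    """Labelled symmetric dissimilarity matrix with a zero diagonal."""

    labels: list[str]
    values: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate labels in distance matrix")
        if not np.allclose(np.diag(self.values), 0.0, atol=_SYM_TOL):
            raise ValidationError("distance matrix diagonal must be zero")
        if not np.allclose(self.values, self.values.T, atol=_SYM_TOL):
            raise ValidationError("distance matrix must be symmetric")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def subset(self, labels: list[str]) -> "DistanceMatrix":
        missing = [l for l in labels if l not in self.labels]
        if missing:
            raise ValidationError(f"labels absent from {self.metric or 'distance'}: {missing}")
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)], self.metric)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.17g")

    @classmethod
    def read_tsv(cls, path: str | Path, metric: str = "") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), metric)


@dataclass
class CognatePairSet:
    """All cushion x bare cross pairs within one site, with dissimilarities."""

    site: str
    pairs: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def dissimilarities(self) -> np.ndarray:
        return np.array([d for _, _, d in self.pairs], dtype=float)


# ---------------------------------------------------------------------------
# distance constructors
# ---------------------------------------------------------------------------


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample rows.

    d(i, j) = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk).  The input must be
    relative or Hellinger transformed; raw counts should be converted first
    so read depth does not masquerade as compositional change.
    """
    if table.mode == "counts":
        raise ValidationError(
            "bray_curtis requires a relative or hellinger table; apply to_relative/hellinger first"
        )
    values = table.values
    dm = squareform(pdist(values, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, dm, metric=f"bray_curtis_{table.mode}")


def jaccard_binary(aflp: AFLPMatrix) -> DistanceMatrix:
    """Jaccard distance between binary fingerprints (double zeros ignored).

    d(i, j) = 1 - a / (a + b + c) with a = shared presences and b, c the
    unilateral presences.
    """
    values = aflp.data.to_numpy(dtype=bool)
    union = (values[:, None, :] | values[None, :, :]).sum(axis=2)
    if (union == 0).any():
        raise ValidationError("pair of fingerprints with empty union")
    inter = (values[:, None, :] & values[None, :, :]).sum(axis=2)
    dm = 1.0 - inter / union
    np.fill_diagonal(dm, 0.0)
    return DistanceMatrix(aflp.individual_ids, dm, metric="jaccard")


def euclidean_standardized(
    chem: SoilChemistry, sample_ids: list[str] | None = None
) -> DistanceMatrix:
    """Euclidean distance on chemistry standardized over the given samples.

    Each of the six variables is centred and scaled to unit variance
    (ddof=1) across exactly the sample set analysed, so a cushion-only
    distance layer is standardized over cushions alone.
    """
    if sample_ids is None:
        sample_ids = chem.sample_ids
    missing = [s for s in sample_ids if s not in chem.data.index]
    if missing:
        raise ValidationError(f"samples absent from chemistry: {missing}")
    if len(sample_ids) < 2:
        raise ValidationError("need at least 2 samples")
    sub = chem.data.loc[sample_ids, list(CHEM_VARS)].to_numpy(dtype=float)
    sd = sub.std(axis=0, ddof=1)
    zero_var = [CHEM_VARS[k] for k in np.flatnonzero(sd == 0)]
    if zero_var:
        raise ValidationError(f"zero-variance chemistry variable(s): {zero_var}")
    z = (sub - sub.mean(axis=0)) / sd
    dm = squareform(pdist(z, metric="euclidean"))
    return DistanceMatrix(list(sample_ids), dm, metric="euclidean_standardized")


def geographic_distance(meta: SampleMetadata, sample_ids: list[str] | None = None) -> DistanceMatrix:
    """Planar Euclidean distance between sample coordinates (metres)."""
    if sample_ids is None:
        sample_ids = meta.sample_ids
    meta.require_samples(sample_ids)
    xy = meta.data.loc[sample_ids, ["x", "y"]].to_numpy(dtype=float)
    if np.isnan(xy).any():
        bad = [sample_ids[k] for k in np.flatnonzero(np.isnan(xy).any(axis=1))]
        raise ValidationError(f"missing coordinates for {bad}")
    dm = squareform(pdist(xy, metric="euclidean"))
    return DistanceMatrix(list(sample_ids), dm, metric="geographic")


def genetic_distance_for_samples(
    aflp_dist: DistanceMatrix, sample_map: dict[str, str]
) -> DistanceMatrix:
    """Re-label a plant-individual distance matrix by cushion sample ids.

    ``sample_map`` pairs each genotyped individual with the cushion soil
    sample collected beneath it; bare soils have no host plant and therefore
    no genetic distance, so the result covers cushion samples only.
    """
    individuals = [i for i in aflp_dist.labels if i in sample_map]
    sub = aflp_dist.subset(individuals)
    samples = [sample_map[i] for i in individuals]
    if len(set(samples)) != len(samples):
        raise ValidationError("two individuals map to the same sample")
    return DistanceMatrix(samples, sub.values, metric=aflp_dist.metric)


def bare_chemistry_distance(
    chem: SoilChemistry, meta: SampleMetadata, cushion_samples: list[str]
) -> DistanceMatrix:
    """Bare-soil chemistry distance attached to cushion samples.

    Each cushion sample is represented by the mean chemistry of the bare
    soils at its site (the undisturbed abiotic environment), standardized
    over the cushion set and compared with Euclidean distance.  Lets
    bare-soil conditions enter cushion-only dissimilarity models.
    """
    meta.require_samples(cushion_samples)
    bare = meta.data[meta.data["location"] == "bare"]
    bare_ids = [s for s in bare.index if s in chem.data.index]
    site_means = chem.data.loc[bare_ids, list(CHEM_VARS)].groupby(bare.loc[bare_ids, "site"]).mean()
    rows = []
    for s in cushion_samples:
        site = meta.data.loc[s, "site"]
        if site not in site_means.index:
            raise ValidationError(f"site {site!r} has no bare-soil chemistry")
        rows.append(site_means.loc[site])
    proxy = pd.DataFrame(rows, index=cushion_samples)
    sd = proxy.std(axis=0, ddof=1)
    zero_var = sd.index[sd == 0].tolist()
    if zero_var:
        raise ValidationError(f"zero-variance chemistry variable(s): {zero_var}")
    z = (proxy - proxy.mean(axis=0)) / sd
    dm = squareform(pdist(z.to_numpy(), metric="euclidean"))
    return DistanceMatrix(list(cushion_samples), dm, metric="euclidean_bare_chemistry")


# ---------------------------------------------------------------------------
# cognate contrasts and diversity
# ---------------------------------------------------------------------------


def cognate_pairs(dist: DistanceMatrix, meta: SampleMetadata) -> list[CognatePairSet]:
    """Within-site cushion x bare pairs and their dissimilarities.

    Sites lacking either location among the labels of ``dist`` are skipped.
    """
    import warnings

    labels = [l for l in dist.labels if l in meta.data.index]
    sub = meta.data.loc[labels]
    out: list[CognatePairSet] = []
    for site, grp in sub.groupby("site", sort=True):
        cushions = grp.index[grp["location"] == "cushion"].tolist()
        bares = grp.index[grp["location"] == "bare"].tolist()
        if not cushions or not bares:
            warnings.warn(f"site {site!r} lacks cushion or bare samples; skipped", stacklevel=2)
            continue
        pairs = [(c, b, dist[(c, b)]) for c in cushions for b in bares]
        out.append(CognatePairSet(site=str(site), pairs=pairs))
    return out


def inverse_simpson(table: AbundanceTable) -> pd.Series:
    """Inverse Simpson diversity per sample: D = 1 / sum_k x_k^2.

    Equals the effective number of equally abundant MOTUs; requires
    relative abundances.
    """
    if table.mode != "relative":
        raise ValidationError("inverse_simpson requires a relative-mode table")
    values = table.values
    return pd.Series(1.0 / (values**2).sum(axis=1), index=table.data.index, name="inverse_simpson")
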
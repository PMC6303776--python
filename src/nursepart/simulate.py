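"""Synthetic datasets with the statistical structure the analyses assume.

The generator emulates a nurse-plant field design: sites on two mountain
massifs (one granitic, one calcareous) whose geography therefore partially
covaries with bedrock, two plant genetic clusters (one restricted to
limestone), paired cushion/bare soil cores at each site, soil chemistry
engineered by the cushions (more strongly by the dense-cushion cluster),
and fungal communities whose composition decays with weighted predictor
distances and carries habitat-specific signature MOTUs.  Every generator is
a pure function of its configuration, including the seed, and provides
ground truth for parameter-recovery and calibration tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core_data import (
    AFLPMatrix,
    AbundanceTable,
    CHEM_VARS,
    HABITATS,
    SampleMetadata,
    SoilChemistry,
    assign_habitats,
)
from .errors import ValidationError
from .gdm import PairTable

__all__ = [
    "SimulationConfig",
    "simulate_metadata",
    "simulate_aflp",
    "simulate_chemistry",
    "simulate_communities",
    "simulate_gdm_pairs",
    "simulate_dataset",
    "write_dataset",
]


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    The default layout mirrors a usable alpine design: 17 sites (9
    granite/exscapa, 5 limestone/exscapa, 3 limestone/longiscapa), five
    cushion and five bare cores per site, 500 MOTUs at a read depth of
    10,000, and 300 AFLP loci.
    """

    seed: int
    n_granite_exscapa: int = 9
    n_limestone_exscapa: int = 5
    n_limestone_longiscapa: int = 3
    samples_per_site_per_location: int = 5
    n_motus: int = 500
    n_loci: int = 300
    read_depth: int = 10_000

    # community model (log scale)
    baseline_sd: float = 1.5
    bedrock_effect_sd: float = 1.0
    spatial_sd: float = 0.5
    spatial_range_m: float = 3000.0
    iid_noise_sd: float = 0.3
    n_signature_per_habitat: int = 10
    signature_boost: float = 6.0
    #: bare habitats host habitat-specific background taxa, not recruits
    bare_signature_boost: float = 3.0
    #: extra boost for each cushion habitat's first signature MOTU, creating
    #: the dominant recruited taxon that depresses diversity beneath cushions
    dominant_extra_boost: float = 3.0
    signature_baseline_offset: float = -2.0

    # soil engineering: exscapa shift vector; longiscapa = exscapa / ratio
    engineering_ratio: float = 3.0
    engineering_scale: float = 1.0

    # AFLP
    aflp_divergence: float = 0.3

    # dissimilarity-regression ground truth
    gdm_weights: tuple[float, ...] = (0.6, 0.15, 0.15, 0.1)
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if any(w < 0 for w in self.gdm_weights):
            raise ValidationError("gdm_weights must be non-negative")
        if self.n_granite_exscapa < 1 or self.n_limestone_longiscapa < 1:
            raise ValidationError("layout must cover >= 2 clusters and >= 2 bedrocks")
        if self.read_depth < 1000:
            raise ValidationError("read depth must be >= 1000")
        if self.n_loci < 50:
            raise ValidationError("need >= 50 AFLP loci")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


# distinct substreams per generator so adding one does not shift the others
_STREAM_META, _STREAM_AFLP, _STREAM_CHEM, _STREAM_COMM = 11, 13, 17, 19

_MASSIF_CENTERS = {"granite": (0.0, 0.0), "limestone": (9000.0, 1500.0)}
_SITE_JITTER_M = 2500.0
_SAMPLE_JITTER_M = 30.0

#: bedrock baselines and measurement noise for the six chemistry variables
_CHEM_BASE = {
    "granite": {"total_n": 0.25, "total_c": 3.0, "water": 0.25, "no3": 2.0, "nh4": 3.0, "ph": 5.0},
    "limestone": {"total_n": 0.30, "total_c": 4.0, "water": 0.30, "no3": 3.5, "nh4": 3.5, "ph": 7.4},
}
_CHEM_NOISE = {"total_n": 0.02, "total_c": 0.25, "water": 0.02, "no3": 0.25, "nh4": 0.25, "ph": 0.12}
#: engineering shift of a cushion relative to bare soil, exscapa cluster;
#: nutrients and water rise beneath cushions, pH rises on acidic granite only
_ENGINEER_SHIFT = {"total_n": 0.20, "total_c": 2.5, "water": 0.15, "no3": 0.0, "nh4": 2.5, "ph": 0.0}
_ENGINEER_PH_GRANITE = 0.8


def _site_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    layout = (
        [("granite", "exscapa")] * config.n_granite_exscapa
        + [("limestone", "exscapa")] * config.n_limestone_exscapa
        + [("limestone", "longiscapa")] * config.n_limestone_longiscapa
    )
    rng = config.rng(_STREAM_META)
    for k, (bedrock, cluster) in enumerate(layout, start=1):
        cx, cy = _MASSIF_CENTERS[bedrock]
        rows.append(
            {
                "site": f"S{k:02d}",
                "bedrock": bedrock,
                "cluster": cluster,
                "site_x": cx + rng.uniform(-_SITE_JITTER_M, _SITE_JITTER_M),
                "site_y": cy + rng.uniform(-_SITE_JITTER_M, _SITE_JITTER_M),
                "elevation": rng.uniform(2300.0, 2900.0),
            }
        )
    return pd.DataFrame(rows).set_index("site")


def simulate_metadata(config: SimulationConfig) -> SampleMetadata:
    """Sample metadata for the full design: sites x (cushion + bare) cores."""
    sites = _site_table(config)
    rng = config.rng(_STREAM_META + 100)
    rows = []
    for site, srow in sites.iterrows():
        for location in ("cushion", "bare"):
            for r in range(1, config.samples_per_site_per_location + 1):
                rows.append(
                    {
                        "sample_id": f"{site}_{location[0]}{r}",
                        "site": site,
                        "bedrock": srow["bedrock"],
                        "location": location,
                        "cluster": srow["cluster"],
                        "elevation": srow["elevation"],
                        "x": srow["site_x"] + rng.uniform(-_SAMPLE_JITTER_M, _SAMPLE_JITTER_M),
                        "y": srow["site_y"] + rng.uniform(-_SAMPLE_JITTER_M, _SAMPLE_JITTER_M),
                    }
                )
    return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))


def simulate_aflp(
    config: SimulationConfig, meta: SampleMetadata
) -> tuple[AFLPMatrix, dict[str, str]]:
    """Binary AFLP fingerprints for one plant per cushion sample.

    Two cluster-specific allele-frequency profiles diverge by
    ``aflp_divergence`` around a shared ancestral frequency, so
    within-cluster Jaccard distances are stochastically smaller than
    between-cluster ones.  Returns the matrix (with its individual-to-sample
    map) and the true cluster label per individual.
    """
    rng = config.rng(_STREAM_AFLP)
    q = rng.uniform(0.15, 0.85, config.n_loci)
    sign = rng.choice([-1.0, 1.0], config.n_loci)
    p_x = np.clip(q + sign * config.aflp_divergence, 0.02, 0.98)
    p_l = np.clip(q - sign * config.aflp_divergence, 0.02, 0.98)
    profiles = {"exscapa": p_x, "longiscapa": p_l}

    cushions = meta.data.index[meta.data["location"] == "cushion"]
    rows, ids, truth = [], [], {}
    sample_map: dict[str, str] = {}
    for sample_id in cushions:
        cluster = meta.data.loc[sample_id, "cluster"]
        if cluster == "ambiguous":
            p = 0.5 * (p_x + p_l)
        else:
            p = profiles[cluster]
        fingerprint = (rng.uniform(size=config.n_loci) < p).astype(int)
        if fingerprint.sum() == 0:  # vanishingly unlikely with >= 50 loci
            fingerprint[int(rng.integers(config.n_loci))] = 1
        individual = f"plant_{sample_id}"
        rows.append(fingerprint)
        ids.append(individual)
        truth[individual] = str(cluster)
        sample_map[individual] = str(sample_id)
    data = pd.DataFrame(
        np.asarray(rows), index=ids, columns=[f"L{j + 1:03d}" for j in range(config.n_loci)]
    )
    return AFLPMatrix(data, sample_map=sample_map), truth


def simulate_chemistry(config: SimulationConfig, meta: SampleMetadata) -> SoilChemistry:
    """Soil chemistry: bedrock baselines + cluster-specific cushion shifts.

    Cushion samples receive the engineering shift vector; the exscapa
    shift exceeds the longiscapa one by ``engineering_ratio`` (default 3).
    pH rises beneath cushions on granite only.
    """
    rng = config.rng(_STREAM_CHEM)
    rows = []
    for sample_id, row in meta.data.iterrows():
        base = _CHEM_BASE[row["bedrock"]]
        values = {}
        if row["location"] == "cushion":
            factor = config.engineering_scale
            if row["cluster"] == "longiscapa":
                factor /= config.engineering_ratio
        else:
            factor = 0.0
        for var in CHEM_VARS:
            shift = _ENGINEER_SHIFT[var]
            if var == "ph" and row["bedrock"] == "granite":
                shift = _ENGINEER_PH_GRANITE
            values[var] = base[var] + factor * shift + rng.normal(0.0, _CHEM_NOISE[var])
        for var in ("total_n", "total_c", "water", "no3", "nh4"):
            values[var] = max(values[var], 0.0)
        values["ph"] = float(np.clip(values["ph"], 3.0, 9.5))
        rows.append({"sample_id": sample_id, **values})
    return SoilChemistry(pd.DataFrame(rows).set_index("sample_id"))


def simulate_communities(
    config: SimulationConfig, meta: SampleMetadata
) -> tuple[AbundanceTable, dict]:
    """Multinomial MOTU count table with planted habitat signatures.

    Per-sample expected composition is a softmax over MOTUs of: a
    log-normal baseline, a bedrock effect, signature boosts for designated
    MOTUs within their habitat, a spatially autocorrelated field tied to
    the sample coordinates, and iid noise.  Counts are multinomial at the
    configured depth.  Returns the counts table and the ground-truth
    signature sets (per habitat, split into cushion and bare).
    """
    rng = config.rng(_STREAM_COMM)
    samples = list(meta.data.index)
    n_s, n_m = len(samples), config.n_motus
    motu_ids = [f"MOTU{j + 1:04d}" for j in range(n_m)]

    baseline = rng.normal(0.0, config.baseline_sd, n_m)
    bedrock_eff = {
        b: rng.normal(0.0, config.bedrock_effect_sd, n_m) for b in ("granite", "limestone")
    }

    habitats = assign_habitats(meta)
    n_sig = config.n_signature_per_habitat
    signature: dict[str, list[str]] = {}
    if n_sig > 0 and config.signature_boost != 0:
        chosen = rng.choice(n_m, size=min(n_sig * len(HABITATS), n_m), replace=False)
        for h_idx, habitat in enumerate(HABITATS):
            idx = chosen[h_idx * n_sig : (h_idx + 1) * n_sig]
            signature[habitat] = [motu_ids[j] for j in idx]
            baseline[idx] = config.signature_baseline_offset + rng.normal(0.0, 0.3, len(idx))
    else:
        signature = {h: [] for h in HABITATS}

    # spatially autocorrelated per-MOTU field (shared Cholesky factor)
    xy = meta.data[["x", "y"]].to_numpy(float)
    if config.spatial_sd > 0:
        dist = squareform(pdist(xy))
        cov = config.spatial_sd**2 * np.exp(-dist / config.spatial_range_m)
        cov[np.diag_indices_from(cov)] += 1e-9
        chol = np.linalg.cholesky(cov)
        spatial = chol @ rng.normal(size=(n_s, n_m))
    else:
        spatial = np.zeros((n_s, n_m))

    sig_index = {
        h: np.array([motu_ids.index(m) for m in motus], dtype=int)
        for h, motus in signature.items()
    }
    sig_boost: dict[str, np.ndarray] = {}
    for h, idx in sig_index.items():
        if h.endswith("c"):
            boosts = np.full(len(idx), config.signature_boost)
            if len(boosts):
                boosts[0] += config.dominant_extra_boost
        else:
            boosts = np.full(len(idx), config.bare_signature_boost)
        sig_boost[h] = boosts
    logits = np.empty((n_s, n_m))
    for i, sample_id in enumerate(samples):
        row = meta.data.loc[sample_id]
        logit = baseline + bedrock_eff.get(row["bedrock"], 0.0) + spatial[i]
        habitat = habitats.get(sample_id)
        if habitat is not None and len(sig_index[habitat]):
            logit = logit.copy()
            logit[sig_index[habitat]] += sig_boost[habitat]
        logits[i] = logit
    logits += rng.normal(0.0, config.iid_noise_sd, size=logits.shape)
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)

    counts = np.vstack([rng.multinomial(config.read_depth, p) for p in probs])
    table = AbundanceTable(
        pd.DataFrame(counts.astype(float), index=samples, columns=motu_ids), mode="counts"
    )
    truth = {
        "signature_by_habitat": signature,
        "cushion_signatures": sorted(
            m for h, motus in signature.items() if h.endswith("c") for m in motus
        ),
        "bare_signatures": sorted(
            m for h, motus in signature.items() if h.endswith("b") for m in motus
        ),
    }
    return table, truth


def simulate_gdm_pairs(
    n_samples: int = 64,
    weights: Sequence[float] = (0.6, 0.15, 0.15, 0.1),
    noise_sd: float = 0.05,
    seed: int = 0,
    predictor_names: Sequence[str] | None = None,
) -> tuple[PairTable, dict[str, float]]:
    """Pairwise regression table with known predictor weights.

    Each predictor distance matrix comes from an independent random planar
    point configuration (scaled to [0, 1]); the response is
    d = 1 - exp(-sum_k w_k x_k) plus Gaussian noise, truncated to [0, 1].
    Returns the table and the true weight per predictor name.
    """
    if not 1 <= len(weights) <= 4:
        raise ValidationError("between 1 and 4 weights")
    if predictor_names is None:
        predictor_names = [f"pred{k + 1}" for k in range(len(weights))]
    rng = np.random.default_rng(seed)
    condensed = {}
    for name in predictor_names:
        pts = rng.uniform(0.0, 1.0, size=(n_samples, 2))
        d = pdist(pts)
        condensed[name] = d / d.max()
    eta = sum(w * condensed[name] for w, name in zip(weights, predictor_names))
    response = 1.0 - np.exp(-eta)
    if noise_sd > 0:
        response = response + rng.normal(0.0, noise_sd, response.shape)
    response = np.clip(response, 0.0, 1.0)
    labels = [f"s{i + 1}" for i in range(n_samples)]
    iu = np.triu_indices(n_samples, k=1)
    pair_labels = [(labels[i], labels[j]) for i, j in zip(*iu)]
    frame = pd.DataFrame({"response": response, **condensed})
    table = PairTable(frame=frame, pair_labels=pair_labels, predictor_names=list(predictor_names))
    return table, dict(zip(predictor_names, weights))


def simulate_dataset(config: SimulationConfig) -> dict:
    """Generate the full linked dataset: metadata, AFLP, chemistry, counts."""
    meta = simulate_metadata(config)
    aflp, cluster_truth = simulate_aflp(config, meta)
    chem = simulate_chemistry(config, meta)
    table, community_truth = simulate_communities(config, meta)
    return {
        "metadata": meta,
        "aflp": aflp,
        "chemistry": chem,
        "abundance": table,
        "truth": {
            "clusters": cluster_truth,
            **community_truth,
            "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        },
    }


def write_dataset(bundle: dict, outdir: str | Path) -> None:
    """Write abundance.tsv, metadata.csv, chemistry.csv, aflp.csv,
    aflp_map.csv and truth.json into ``outdir``."""
    from . import core_data

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    core_data.write_abundance(bundle["abundance"], outdir / "abundance.tsv")
    core_data.write_metadata(bundle["metadata"], outdir / "metadata.csv")
    core_data.write_chemistry(bundle["chemistry"], outdir / "chemistry.csv")
    core_data.write_aflp(bundle["aflp"], outdir / "aflp.csv", outdir / "aflp_map.csv")
    (outdir / "truth.json").write_text(json.dumps(bundle["truth"], indent=2, sort_keys=True))
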
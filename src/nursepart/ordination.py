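"""Descriptive ordinations and soil-engineering summaries.

PCA of standardized soil chemistry, non-metric multidimensional scaling
(NMDS) of community dissimilarities with environmental vector fitting, and
per-group summaries of the cognate cushion/bare contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .core_data import CHEM_VARS, SampleMetadata, SoilChemistry
from .dissimilarity import DistanceMatrix, cognate_pairs, euclidean_standardized
from .errors import ValidationError


@dataclass
class OrdinationResult:
    """Scores plus method-specific extras (variance fractions / stress / vectors)."""

    scores: pd.DataFrame  # samples x axes
    axis_variance: np.ndarray | None = None  # PCA
    loadings: pd.DataFrame | None = None  # PCA
    stress: float | None = None  # NMDS
    stress_trace: list[float] = field(default_factory=list)  # best-start trace
    vectors: pd.DataFrame | None = None  # envfit


# ---------------------------------------------------------------------------
# PCA of chemistry
# ---------------------------------------------------------------------------


def pca_chemistry(chem: SoilChemistry, sample_ids: Sequence[str] | None = None) -> OrdinationResult:
    """PCA on centred, unit-variance chemistry (correlation-matrix PCA)."""
    ids = list(sample_ids) if sample_ids is not None else chem.sample_ids
    if len(ids) < 3:
        raise ValidationError("need at least 3 samples for PCA")
    X = chem.data.loc[ids, list(CHEM_VARS)].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    zero = [CHEM_VARS[k] for k in np.flatnonzero(sd == 0)]
    if zero:
        raise ValidationError(f"zero-variance chemistry variable(s): {zero}")
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-magnitude loading positive on each axis
    for j in range(eigvec.shape[1]):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] *= -1
    scores = Z @ eigvec
    axes = [f"PC{j + 1}" for j in range(len(eigval))]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=ids, columns=axes),
        axis_variance=eigval / eigval.sum(),
        loadings=pd.DataFrame(eigvec, index=list(CHEM_VARS), columns=axes),
    )


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


def _kruskal_stress(d_config: np.ndarray, disparities: np.ndarray) -> float:
    denom = float(d_config @ d_config)
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d_config - disparities) ** 2).sum() / denom))


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    seed: int = 0,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Alternates isotonic (monotone) regression of configuration distances on
    the observed dissimilarities with a Guttman majorization step, from
    ``n_starts`` random configurations; the best final stress wins.
    Deterministic under a fixed seed.
    """
    delta = dist.condensed()
    n = len(dist.labels)
    if n < 3:
        raise ValidationError("need at least 3 samples for NMDS")
    order = np.argsort(delta, kind="stable")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, list[float]] | None = None
    for _ in range(n_starts):
        X = rng.normal(size=(n, k))
        trace: list[float] = []
        prev = np.inf
        for _ in range(max_iter):
            d = pdist(X)
            iso = IsotonicRegression(increasing=True)
            dhat = np.empty_like(d)
            dhat[order] = iso.fit_transform(np.arange(len(d)), d[order])
            stress = _kruskal_stress(d, dhat)
            trace.append(stress)
            if stress < 1e-5 or prev - stress < tol:
                break
            prev = stress
            # Guttman transform with weights 1 and disparities dhat
            D = squareform(d)
            ratio = np.zeros_like(D)
            nonzero = D > 0
            ratio[nonzero] = squareform(dhat)[nonzero] / D[nonzero]
            B = -ratio
            np.fill_diagonal(B, ratio.sum(axis=1))
            X = (B @ X) / n
        else:
            if trace[-1] > 0.05:  # still-poor configuration worth flagging
                warnings.warn(
                    f"NMDS start did not converge in {max_iter} iterations "
                    f"(last stress {trace[-1]:.4g})",
                    stacklevel=2,
                )
        if best is None or trace[-1] < best[0]:
            best = (trace[-1], X, trace)
    assert best is not None
    stress, X, trace = best
    # centre and rotate to principal axes for a canonical orientation
    X = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    for j in range(vt.shape[0]):
        if vt[j, np.argmax(np.abs(vt[j]))] < 0:
            vt[j] *= -1
    X = X @ vt.T
    axes = [f"NMDS{j + 1}" for j in range(k)]
    return OrdinationResult(
        scores=pd.DataFrame(X, index=dist.labels, columns=axes),
        stress=stress,
        stress_trace=trace,
    )


# ---------------------------------------------------------------------------
# environmental vector fitting
# ---------------------------------------------------------------------------


def envfit(
    scores: pd.DataFrame,
    variables: pd.DataFrame,
    B: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit environmental vectors onto ordination scores.

    For each variable, the least-squares direction in score space and the
    fraction of variable variance explained (R^2); significance by
    permuting the variable across samples.
    """
    common = [s for s in scores.index if s in variables.index]
    if len(common) < 3:
        raise ValidationError("scores and variables share fewer than 3 samples")
    S = scores.loc[common].to_numpy(dtype=float)
    S_centered = S - S.mean(axis=0)
    pinv = np.linalg.pinv(S_centered)
    rng = np.random.default_rng(seed)
    rows = []
    for name in variables.columns:
        v = variables.loc[common, name].to_numpy(dtype=float)
        if v.std() == 0:
            raise ValidationError(f"constant variable {name!r}")
        vc = v - v.mean()

        def r2_of(vec: np.ndarray) -> tuple[float, np.ndarray]:
            coef = pinv @ vec
            fitted = S_centered @ coef
            tss = float(vec @ vec)
            return float((fitted @ fitted) / tss), coef

        r2, coef = r2_of(vc)
        norm = np.linalg.norm(coef)
        direction = coef / norm if norm > 0 else coef
        exceed = 0
        for _ in range(B):
            vp = vc[rng.permutation(len(vc))]
            r2_b, _ = r2_of(vp)
            exceed += r2_b >= r2 - 1e-15
        p = (1.0 + exceed) / (1.0 + B)
        rows.append(
            {"variable": name, "r2": r2, "p": p, **{f"d_{ax}": d for ax, d in zip(scores.columns, direction)}}
        )
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# engineering summaries
# ---------------------------------------------------------------------------


def engineering_summary(
    chem: SoilChemistry,
    community: DistanceMatrix,
    meta: SampleMetadata,
    site_means: bool = False,
) -> dict:
    """Per bedrock x cluster group summaries of cognate cushion/bare shifts.

    Returns distributions of cognate-pair chemistry distances and community
    dissimilarities per group, pairwise two-sided Mann-Whitney comparisons
    between groups, and per-variable cushion-minus-bare site contrasts.
    With ``site_means=True`` the rank-sum comparisons use one mean value
    per site, avoiding pseudo-replication of pairs within sites.
    """
    samples = [s for s in community.labels if s in chem.data.index and s in meta.data.index]
    chem_dist = euclidean_standardized(chem, samples)
    comm = community.subset(samples)

    chem_sets = cognate_pairs(chem_dist, meta)
    comm_sets = cognate_pairs(comm, meta)

    site_info = meta.data.loc[samples].groupby("site").agg(
        bedrock=("bedrock", "first"), cluster=("cluster", "first")
    )

    def collect(pair_sets) -> pd.DataFrame:
        rows = []
        for ps in pair_sets:
            if ps.site not in site_info.index:
                continue
            bedrock = site_info.loc[ps.site, "bedrock"]
            cluster = site_info.loc[ps.site, "cluster"]
            vals = ps.dissimilarities
            if site_means:
                vals = np.array([vals.mean()])
            for v in vals:
                rows.append(
                    {"site": ps.site, "group": f"{cluster}/{bedrock}", "value": float(v)}
                )
        return pd.DataFrame(rows)

    chem_df = collect(chem_sets)
    comm_df = collect(comm_sets)

    def compare(df: pd.DataFrame) -> pd.DataFrame:
        rows = []
        groups = sorted(df["group"].unique())
        for i, g1 in enumerate(groups):
            for g2 in groups[i + 1 :]:
                a = df.loc[df["group"] == g1, "value"]
                b = df.loc[df["group"] == g2, "value"]
                if len(a) < 2 or len(b) < 2:
                    warnings.warn(f"group pair {g1}/{g2} too small; skipped", stacklevel=2)
                    continue
                stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                rows.append(
                    {
                        "group1": g1,
                        "group2": g2,
                        "mean1": a.mean(),
                        "mean2": b.mean(),
                        "u": float(stat),
                        "p": float(p),
                    }
                )
        return pd.DataFrame(rows)

    # per-variable cushion-minus-bare site contrasts
    contrast_rows = []
    sub = meta.data.loc[samples]
    for site, grp in sub.groupby("site"):
        cushions = grp.index[grp["location"] == "cushion"]
        bares = grp.index[grp["location"] == "bare"]
        if len(cushions) == 0 or len(bares) == 0:
            continue
        row = {
            "site": site,
            "group": f"{site_info.loc[site, 'cluster']}/{site_info.loc[site, 'bedrock']}",
        }
        for var in CHEM_VARS:
            row[var] = float(
                chem.data.loc[cushions, var].mean() - chem.data.loc[bares, var].mean()
            )
        contrast_rows.append(row)
    contrasts = pd.DataFrame(contrast_rows)

    return {
        "chemistry_shifts": chem_df,
        "community_shifts": comm_df,
        "chemistry_comparisons": compare(chem_df),
        "community_comparisons": compare(comm_df),
        "variable_contrasts": contrasts,
    }
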
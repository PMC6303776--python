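"""Habitat-association tests for MOTUs and taxon-level abundance shifts.

A MOTU "occurs" in a sample when its relative abundance strictly exceeds a
frequency threshold (default 0.1%).  Occurrences are cross-tabulated over
the six habitats, habitat-independence is tested with a chi-square statistic
whose null distribution comes from permuting sample habitat labels, p-values
are Benjamini-Hochberg corrected, and MOTUs positively associated with at
least one cushion habitat (Pearson residual > 2) but no bare habitat are
flagged as plant-associated.

Taxon-group abundance shifts beneath vs. outside cushions are tested with a
likelihood-ratio comparison of linear mixed models sharing a random site
intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_data import AbundanceTable, BARE_HABITATS, CUSHION_HABITATS
from .errors import ValidationError


@dataclass
class OccurrenceTable:
    """Per-MOTU occurrence counts per habitat plus habitat sample sizes."""

    counts: pd.DataFrame  # motus x habitats
    sizes: pd.Series  # samples per habitat
    threshold: float

    def __post_init__(self) -> None:
        if (self.sizes <= 0).any():
            empty = self.sizes.index[self.sizes <= 0].tolist()
            raise ValidationError(f"habitat(s) with zero samples: {empty}")
        over = (self.counts > self.sizes).any(axis=1)
        if over.any():
            raise ValidationError("occurrence count exceeds habitat size")


@dataclass
class AssociationResult:
    motu_id: str
    chi2: float
    p_perm: float
    p_adj: float
    residuals: pd.Series  # per-habitat Pearson residual of the 'present' row
    degenerate: bool = False
    selected: bool = False
    driving_habitats: tuple[str, ...] = ()


def occurrence_counts(
    table: AbundanceTable,
    habitats: Mapping[str, str],
    threshold: float = 0.001,
) -> OccurrenceTable:
    """Count, per MOTU and habitat, samples with abundance strictly > threshold."""
    if table.mode != "relative":
        raise ValidationError("occurrence_counts requires a relative-mode table")
    samples = [s for s in table.sample_ids if s in habitats]
    if not samples:
        raise ValidationError("no samples covered by the habitat map")
    sub = table.data.loc[samples]
    labels = pd.Series([habitats[s] for s in samples], index=samples)
    habitat_order = sorted(labels.unique())
    occ = (sub > threshold).astype(int)
    counts = occ.groupby(labels).sum().T  # motus x habitats
    counts = counts[habitat_order]
    sizes = labels.value_counts().reindex(habitat_order)
    return OccurrenceTable(counts=counts, sizes=sizes.astype(int), threshold=threshold)


def _chi2_many(counts: np.ndarray, sizes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized 2 x h chi-square over MOTUs (rows of ``counts``).

    Returns (chi2, present-row Pearson residuals, degenerate flag).  A MOTU
    present in every sample or in none has fixed margins and gets chi2 = 0.
    """
    counts = np.asarray(counts, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    n_total = sizes.sum()
    present = counts.sum(axis=1)
    degenerate = (present == 0) | (present == n_total)
    expected = np.outer(present, sizes) / n_total  # E for the 'present' row
    expected_absent = sizes[None, :] - expected
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = counts - expected
        chi2 = (diff**2 / expected + diff**2 / expected_absent).sum(axis=1)
        residuals = diff / np.sqrt(expected)
    chi2 = np.where(degenerate, 0.0, chi2)
    residuals = np.where(degenerate[:, None], 0.0, residuals)
    return chi2, residuals, degenerate


def chi_square(occ: OccurrenceTable) -> pd.DataFrame:
    """Chi-square of habitat independence per MOTU, with Pearson residuals.

    Each MOTU forms a 2 x h (present/absent by habitat) contingency table;
    expected counts come from the margins and residuals are reported for
    the 'present' row.
    """
    chi2, residuals, degenerate = _chi2_many(occ.counts.to_numpy(), occ.sizes.to_numpy())
    out = pd.DataFrame(
        {"chi2": chi2, "degenerate": degenerate},
        index=occ.counts.index,
    )
    for j, h in enumerate(occ.counts.columns):
        out[f"residual_{h}"] = residuals[:, j]
    return out


def permutation_test(
    table: AbundanceTable,
    habitats: Mapping[str, str],
    B: int = 10_000,
    seed: int = 0,
    threshold: float = 0.001,
    unit: str = "samples",
    sites: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Permutation p-values for the habitat chi-square, per MOTU.

    Habitat labels are permuted across samples ``B`` times with one shared
    permutation stream; all MOTU statistics are recomputed per permutation
    and p = (1 + #{chi2_b >= chi2_obs}) / (1 + B).

    With ``unit='sites'`` (requires ``sites`` mapping sample -> site) the
    site-level habitat prefix (plant cluster + bedrock) is permuted across
    sites while each sample keeps its cushion/bare location, a conservative
    alternative when samples within a site are correlated.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    occ_table = occurrence_counts(table, habitats, threshold)
    samples = [s for s in table.sample_ids if s in habitats]
    sub = (table.data.loc[samples] > threshold).to_numpy(dtype=float)
    habitat_order = list(occ_table.counts.columns)
    label_idx = np.array([habitat_order.index(habitats[s]) for s in samples])
    onehot = np.eye(len(habitat_order))[label_idx]  # samples x habitats
    sizes = occ_table.sizes.to_numpy()

    chi2_obs, residuals, degenerate = _chi2_many(occ_table.counts.to_numpy(), sizes)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(chi2_obs))
    occ_t = sub.T  # motus x samples

    if unit == "samples":
        def permuted_onehot() -> np.ndarray:
            return onehot[rng.permutation(len(samples))]
    elif unit == "sites":
        if sites is None:
            raise ValidationError("unit='sites' requires the sample -> site mapping")
        site_of = [sites[s] for s in samples]
        site_list = sorted(set(site_of))
        prefix_of_site = {}
        for s, site in zip(samples, site_of):
            prefix_of_site.setdefault(site, habitats[s][:-1])
        base_prefixes = [prefix_of_site[site] for site in site_list]
        site_idx = np.array([site_list.index(site) for site in site_of])
        location_letter = np.array([habitats[s][-1] for s in samples])

        def permuted_onehot() -> np.ndarray:
            shuffled = [base_prefixes[k] for k in rng.permutation(len(site_list))]
            codes = [shuffled[site_idx[i]] + location_letter[i] for i in range(len(samples))]
            idx = np.array([habitat_order.index(c) for c in codes])
            return np.eye(len(habitat_order))[idx]
    else:
        raise ValidationError(f"unknown permutation unit {unit!r}")

    for _ in range(B):
        oh = permuted_onehot()
        counts_b = occ_t @ oh
        # habitat sizes can shift under site-level permutation of unequal sites
        chi2_b, _, _ = _chi2_many(counts_b, oh.sum(axis=0))
        exceed += chi2_b >= chi2_obs - 1e-12
    p_perm = (1.0 + exceed) / (1.0 + B)

    out = pd.DataFrame(
        {"chi2": chi2_obs, "p_perm": p_perm, "degenerate": degenerate},
        index=occ_table.counts.index,
    )
    for j, h in enumerate(habitat_order):
        out[f"residual_{h}"] = residuals[:, j]
    return out


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def select_plant_associated(
    results: pd.DataFrame,
    alpha: float = 0.05,
    residual_cut: float = 2.0,
    cushion_habitats: Sequence[str] = CUSHION_HABITATS,
    bare_habitats: Sequence[str] = BARE_HABITATS,
    p_column: str = "p_adj",
) -> pd.DataFrame:
    """Apply the cushion-association selection rule.

    A MOTU is selected when its (FDR-adjusted) permutation p-value falls
    below ``alpha``, at least one cushion habitat has Pearson residual
    above ``residual_cut``, and no bare habitat does.  The cushion
    habitat(s) driving the selection are annotated.
    """
    results = results.copy()
    if p_column not in results.columns:
        raise ValidationError(f"results lack column {p_column!r}")
    cushion_cols = [f"residual_{h}" for h in cushion_habitats if f"residual_{h}" in results]
    bare_cols = [f"residual_{h}" for h in bare_habitats if f"residual_{h}" in results]
    if not cushion_cols:
        raise ValidationError("no cushion-habitat residual columns present")
    sig = results[p_column] < alpha
    cushion_hit = (results[cushion_cols] > residual_cut).any(axis=1)
    bare_hit = (results[bare_cols] > residual_cut).any(axis=1) if bare_cols else False
    results["selected"] = sig & cushion_hit & ~bare_hit
    driving = []
    for _, row in results.iterrows():
        if row["selected"]:
            driving.append(
                ",".join(
                    h
                    for h in cushion_habitats
                    if f"residual_{h}" in results and row[f"residual_{h}"] > residual_cut
                )
            )
        else:
            driving.append("")
    results["driving_habitats"] = driving
    return results


def associate(
    table: AbundanceTable,
    habitats: Mapping[str, str],
    threshold: float = 0.001,
    B: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    residual_cut: float = 2.0,
) -> pd.DataFrame:
    """Full association pipeline: occurrences, permutation chi-square, FDR,
    selection.  Returns one row per MOTU sorted by adjusted p-value."""
    results = permutation_test(table, habitats, B=B, seed=seed, threshold=threshold)
    results["p_adj"] = fdr_adjust(results["p_perm"].to_numpy())
    results = select_plant_associated(results, alpha=alpha, residual_cut=residual_cut)
    return results.sort_values(["p_adj", "p_perm"]).rename_axis("motu_id")


# ---------------------------------------------------------------------------
# taxon-level abundance shifts (mixed models)
# ---------------------------------------------------------------------------


def taxon_shift_test(
    abundance: Sequence[float],
    location: Sequence[str],
    site: Sequence[str],
    n_perm_fallback: int = 999,
    seed: int = 0,
) -> dict:
    """Cushion-vs-bare shift test for one taxon group's relative abundance.

    Compares, by likelihood ratio under maximum likelihood, a null mixed
    model (intercept + random site intercept) against one adding location
    as a fixed effect; p comes from chi-square with 1 df.  If the mixed
    model is degenerate (e.g. zero residual variation), a site-stratified
    permutation of location labels is used instead and flagged.
    """
    import statsmodels.api as sm

    y = np.asarray(abundance, dtype=float)
    loc = pd.Series(location).astype(str)
    sites = pd.Series(site).astype(str)
    if sites.nunique() < 2:
        raise ValidationError("need at least 2 sites")
    if set(loc.unique()) - {"cushion", "bare"}:
        raise ValidationError("location labels must be 'cushion'/'bare'")
    if loc.nunique() < 2:
        raise ValidationError("both locations must be present")
    x = (loc == "cushion").to_numpy(dtype=float)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null = sm.MixedLM(y, np.ones((len(y), 1)), groups=sites).fit(reml=False)
            full = sm.MixedLM(y, np.column_stack([np.ones(len(y)), x]), groups=sites).fit(
                reml=False
            )
        stat = 2.0 * (full.llf - null.llf)
        if not np.isfinite(stat):
            raise ValueError("non-finite likelihood")
        stat = max(stat, 0.0)
        p = float(stats.chi2.sf(stat, df=1))
        return {"stat": float(stat), "p": p, "method": "lrt"}
    except (ValueError, np.linalg.LinAlgError):
        rng = np.random.default_rng(seed)
        obs = abs(y[x == 1].mean() - y[x == 0].mean())
        exceed = 0
        site_codes = sites.to_numpy()
        for _ in range(n_perm_fallback):
            x_perm = np.empty_like(x)
            for s in np.unique(site_codes):
                idx = np.flatnonzero(site_codes == s)
                x_perm[idx] = x[rng.permutation(idx)]
            stat_b = abs(y[x_perm == 1].mean() - y[x_perm == 0].mean())
            exceed += stat_b >= obs - 1e-15
        p = (1.0 + exceed) / (1.0 + n_perm_fallback)
        return {"stat": float(obs), "p": float(p), "method": "permutation"}


def taxon_shift_tests(
    groups: pd.DataFrame,
    location: Sequence[str],
    site: Sequence[str],
    seed: int = 0,
) -> pd.DataFrame:
    """Apply :func:`taxon_shift_test` to each column and BH-adjust p-values."""
    rows = []
    for name in groups.columns:
        res = taxon_shift_test(groups[name].to_numpy(), location, site, seed=seed)
        rows.append({"group": name, **res})
    out = pd.DataFrame(rows).set_index("group")
    out["p_adj"] = fdr_adjust(out["p"].to_numpy())
    return out
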
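"""Generalized dissimilarity models and pure/joint variance partitioning.

Community dissimilarity between pairs of samples is regressed on monotone
spline transforms of up to four pairwise predictor distances (plant genetic
distance, cushion- and bare-soil chemistry distance, geographic distance).
Explained variance per predictor subset is summarised with Nagelkerke's
pseudo-R^2, and the 2^p - 1 subset fits are combined into an exclusive
(Venn-region) decomposition: the pure fraction of a predictor is its effect
after accounting for all others, the joint fractions the variance shared by
each specific predictor subset.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import lsq_linear, minimize

from .dissimilarity import DistanceMatrix
from .errors import FitError, ValidationError


# ---------------------------------------------------------------------------
# monotone spline basis
# ---------------------------------------------------------------------------


@dataclass
class ISplineBasis:
    """Monotone I-spline basis for one predictor distance.

    ``n_splines`` nondecreasing basis functions, each rising from 0 to 1
    over the observed predictor range, built as reversed cumulative sums of
    a quadratic B-spline partition of unity.  Knots sit at the requested
    quantiles of the observed distances (default 0, 0.5, 1, i.e. min /
    median / max), so with non-negative coefficients any fitted curve is a
    monotone distance-decay transform.
    """

    knots: np.ndarray  # interior + boundary knots, ascending
    degree: int = 2

    @classmethod
    def from_data(
        cls, x: np.ndarray, n_splines: int = 3, quantiles: Sequence[float] | None = None
    ) -> "ISplineBasis":
        x = np.asarray(x, dtype=float)
        if quantiles is None:
            # a degree-2 basis on K distinct knots yields K monotone ramps,
            # so the default 3 functions use knot quantiles (0, 0.5, 1)
            quantiles = np.linspace(0.0, 1.0, n_splines)
        knots = np.quantile(x, quantiles)
        lo, hi = knots[0], knots[-1]
        if hi <= lo:
            raise ValidationError("predictor distances are constant; no spline basis")
        # guard against ties collapsing interior knots onto the boundary
        inner = knots[1:-1]
        eps = (hi - lo) * 1e-9
        inner = np.clip(inner, lo + eps, hi - eps)
        for k in range(1, len(inner)):
            inner[k] = max(inner[k], inner[k - 1] + eps)
        return cls(knots=np.concatenate(([lo], inner, [hi])))

    @property
    def n_splines(self) -> int:
        return len(self.knots)

    def design(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the basis: returns an (n, n_splines) monotone design."""
        x = np.clip(np.asarray(x, dtype=float), self.knots[0], self.knots[-1])
        d = self.degree
        t = np.concatenate((np.repeat(self.knots[0], d), self.knots, np.repeat(self.knots[-1], d)))
        full = BSpline.design_matrix(x, t, d, extrapolate=False).toarray()
        # reversed cumulative sums of the partition of unity; drop the
        # constant (sum over all columns = 1), leaving monotone 0 -> 1 ramps
        rev = np.cumsum(full[:, ::-1], axis=1)[:, ::-1]
        return rev[:, 1:]


# ---------------------------------------------------------------------------
# pair table
# ---------------------------------------------------------------------------


@dataclass
class PairTable:
    """One row per unordered sample pair: response and predictor distances."""

    frame: pd.DataFrame  # columns: response + predictor names
    pair_labels: list[tuple[str, str]]
    predictor_names: list[str]

    def __post_init__(self) -> None:
        if "response" not in self.frame.columns:
            raise ValidationError("pair table needs a 'response' column")
        if self.frame.isna().any().any():
            raise ValidationError("pair table contains missing values")
        resp = self.frame["response"].to_numpy(float)
        if ((resp < 0) | (resp > 1)).any():
            raise ValidationError("response dissimilarities must lie in [0, 1]")

    @property
    def n_pairs(self) -> int:
        return len(self.frame)

    @property
    def response(self) -> np.ndarray:
        return self.frame["response"].to_numpy(float)

    def predictor(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy(float)


def build_pair_table(
    response: DistanceMatrix,
    predictors: Mapping[str, DistanceMatrix],
    sample_subset: Sequence[str] | None = None,
) -> PairTable:
    """Assemble the pairwise regression table over a sample subset.

    All matrices must cover the subset; every unordered pair (i < j)
    becomes one row.
    """
    if sample_subset is None:
        sample_subset = response.labels
    samples = list(sample_subset)
    if len(set(predictors)) != len(predictors):
        raise ValidationError("duplicate predictor names")
    layers = {"response": response, **predictors}
    mats = {}
    for name, dm in layers.items():
        missing = [s for s in samples if s not in dm.labels]
        if missing:
            raise ValidationError(f"layer {name!r} missing samples {missing}")
        mats[name] = dm.subset(samples).values
    iu = np.triu_indices(len(samples), k=1)
    data = {name: mat[iu] for name, mat in mats.items()}
    pair_labels = [(samples[i], samples[j]) for i, j in zip(*iu)]
    return PairTable(
        frame=pd.DataFrame(data),
        pair_labels=pair_labels,
        predictor_names=list(predictors),
    )


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


@dataclass
class SplineConfig:
    n_splines: int = 3
    quantiles: Sequence[float] | None = None


@dataclass
class LikelihoodConfig:
    """Likelihood / link used for the dissimilarity regression.

    ``link='identity'`` (default) fits E[d] = beta0 + sum_m beta_m F_m by
    bounded least squares; ``link='negexp'`` fits the classical
    generalized-dissimilarity curve E[d] = 1 - exp(-eta) by bounded
    quasi-Newton from a zero start.  Both use a Gaussian likelihood with
    the error variance profiled out, so the subset R^2 is a smooth monotone
    transform of the residual sum of squares.
    """

    link: str = "identity"
    tol: float = 1e-9


@dataclass
class GDMFit:
    subset: tuple[str, ...]
    intercept: float
    coefficients: dict[str, np.ndarray]
    bases: dict[str, ISplineBasis]
    loglik: float
    null_loglik: float
    n_pairs: int
    nagelkerke_r2: float
    rss: float
    link: str = "identity"

    def predict(self, pairs: PairTable) -> np.ndarray:
        eta = np.full(pairs.n_pairs, self.intercept)
        for name in self.subset:
            design = self.bases[name].design(pairs.predictor(name))
            eta = eta + design @ self.coefficients[name]
        if self.link == "negexp":
            return 1.0 - np.exp(-eta)
        return eta


def _gaussian_loglik(rss: float, n: int) -> float:
    # profile log-likelihood of a Gaussian with sigma^2 = RSS / n
    sigma2 = max(rss / n, 1e-300)
    return -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)


def fit_gdm(
    pairs: PairTable,
    subset: Sequence[str] = (),
    spline_config: SplineConfig | None = None,
    likelihood_config: LikelihoodConfig | None = None,
) -> GDMFit:
    """Fit a monotone dissimilarity model on a subset of predictors.

    The linear predictor combines an unconstrained intercept with
    non-negative coefficients on the monotone I-spline columns of each
    predictor in ``subset``; an empty subset gives the intercept-only null
    model.  Nagelkerke's R^2 compares the fitted and null likelihoods; for
    the Gaussian likelihood used here the attainable maximum of the
    Cox-Snell ratio is 1, so the statistic reduces to 1 - RSS/RSS0.
    """
    spline_config = spline_config or SplineConfig()
    likelihood_config = likelihood_config or LikelihoodConfig()
    subset = tuple(subset)
    unknown = [s for s in subset if s not in pairs.predictor_names]
    if unknown:
        raise ValidationError(f"unknown predictors {unknown}")
    y = pairs.response
    n = pairs.n_pairs

    bases: dict[str, ISplineBasis] = {}
    blocks: list[np.ndarray] = []
    for name in subset:
        basis = ISplineBasis.from_data(
            pairs.predictor(name), spline_config.n_splines, spline_config.quantiles
        )
        bases[name] = basis
        blocks.append(basis.design(pairs.predictor(name)))
    X = np.hstack([np.ones((n, 1))] + blocks) if blocks else np.ones((n, 1))
    k = X.shape[1]

    if likelihood_config.link == "identity":
        lower = np.full(k, 0.0)
        lower[0] = -np.inf
        res = lsq_linear(X, y, bounds=(lower, np.full(k, np.inf)), method="bvls", tol=1e-14)
        if not res.success and res.status <= 0:
            raise FitError(f"bounded least squares failed for subset {subset}: {res.message}")
        beta = res.x
        resid = y - X @ beta
        rss = float(resid @ resid)
    elif likelihood_config.link == "negexp":

        def objective(b: np.ndarray) -> tuple[float, np.ndarray]:
            eta = X @ b
            mu = 1.0 - np.exp(-eta)
            r = y - mu
            grad = -2.0 * X.T @ (r * np.exp(-eta))
            return float(r @ r), grad

        bounds = [(None, None)] + [(0.0, None)] * (k - 1)
        res = minimize(
            objective,
            x0=np.zeros(k),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": likelihood_config.tol, "gtol": 1e-10, "maxiter": 2000},
        )
        if not res.success:
            raise FitError(f"negexp fit failed for subset {subset}: {res.message}")
        beta = res.x
        rss = float(res.fun)
    else:
        raise ValidationError(f"unknown link {likelihood_config.link!r}")

    y_centered = y - y.mean()
    rss0 = float(y_centered @ y_centered)
    loglik = _gaussian_loglik(rss, n)
    null_loglik = _gaussian_loglik(rss0, n)
    if rss0 <= 0:
        r2 = 0.0
    else:
        # Cox-Snell ratio 1 - exp(2(l0 - l)/n) = 1 - RSS/RSS0; its maximum
        # for a continuous likelihood is 1, so no further rescaling
        r2 = 1.0 - rss / rss0
    r2 = float(min(1.0, max(0.0, r2)))

    coefficients = {}
    offset = 1
    for name in subset:
        width = bases[name].n_splines
        coefficients[name] = beta[offset : offset + width]
        offset += width
    return GDMFit(
        subset=subset,
        intercept=float(beta[0]),
        coefficients=coefficients,
        bases=bases,
        loglik=loglik,
        null_loglik=null_loglik,
        n_pairs=n,
        nagelkerke_r2=r2,
        rss=rss,
        link=likelihood_config.link,
    )


# ---------------------------------------------------------------------------
# variance partitioning
# ---------------------------------------------------------------------------


@dataclass
class PartitionResult:
    """Pure/joint (Venn-region) decomposition of subset-wise R^2 values.

    ``r2_by_subset`` maps every non-empty predictor subset S to its
    Nagelkerke R^2; ``region_values`` maps every non-empty subset T to the
    exclusive region value c(T) solving R(S) = sum over T intersecting S of
    c(T).  Pure fractions are the singleton regions; joint regions may be
    negative (suppression) and are reported as-is.
    """

    predictors: tuple[str, ...]
    r2_by_subset: dict[tuple[str, ...], float]
    region_values: dict[tuple[str, ...], float]

    @property
    def total_r2(self) -> float:
        return self.r2_by_subset[self.predictors]

    @property
    def pure_fractions(self) -> dict[str, float]:
        return {p: self.region_values[(p,)] for p in self.predictors}

    @property
    def unexplained(self) -> float:
        return 1.0 - self.total_r2


def _subsets(names: Sequence[str]) -> list[tuple[str, ...]]:
    out: list[tuple[str, ...]] = []
    for r in range(1, len(names) + 1):
        out.extend(itertools.combinations(names, r))
    return out


def partition_variance(
    pairs: PairTable,
    predictors: Sequence[str] | None = None,
    spline_config: SplineConfig | None = None,
    likelihood_config: LikelihoodConfig | None = None,
) -> PartitionResult:
    """Decompose explained variance into exclusive pure and joint regions.

    Fits all 2^p - 1 non-empty predictor subsets (p <= 4) and solves the
    linear system R(S) = sum_{T : T intersects S} c(T) for the region
    values.  With two predictors this reduces to the classical commonality
    formulas c({1}) = R({1,2}) - R({2}) and
    c({1,2}) = R({1}) + R({2}) - R({1,2}).
    """
    if predictors is None:
        predictors = pairs.predictor_names
    predictors = tuple(predictors)
    if not 1 <= len(predictors) <= 4:
        raise ValidationError("partition_variance supports 1 to 4 predictors")
    subsets = _subsets(predictors)
    r2: dict[tuple[str, ...], float] = {}
    for S in subsets:
        try:
            r2[S] = fit_gdm(pairs, S, spline_config, likelihood_config).nagelkerke_r2
        except FitError as exc:
            raise FitError(f"subset {S} failed: {exc}") from exc

    m = len(subsets)
    A = np.zeros((m, m))
    b = np.zeros(m)
    for i, S in enumerate(subsets):
        b[i] = r2[S]
        s_set = set(S)
        for j, T in enumerate(subsets):
            if s_set & set(T):
                A[i, j] = 1.0
    c = np.linalg.solve(A, b)
    regions = {T: float(c[j]) for j, T in enumerate(subsets)}
    return PartitionResult(predictors=predictors, r2_by_subset=r2, region_values=regions)


def venn_report(result: PartitionResult) -> dict:
    """Serializable report of region values, subset R^2 and totals."""
    key = lambda T: "&".join(T)
    return {
        "predictors": list(result.predictors),
        "r2_by_subset": {key(S): v for S, v in result.r2_by_subset.items()},
        "region_values": {key(T): v for T, v in result.region_values.items()},
        "pure_fractions": dict(result.pure_fractions),
        "total_r2": result.total_r2,
        "unexplained": result.unexplained,
    }


def write_venn_report(result: PartitionResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(venn_report(result), indent=2, sort_keys=True))


def read_venn_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
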
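"""Used–available resource selection functions with blocked cross-validation.

The design contrasts each animal's relocations (case = 1) against random
points from its availability domain (case = 0, default 10 per presence,
weighted heavily so the logistic fit approximates the underlying point-process
likelihood). Covariates are distances to landscape features, log-transformed
and standardized on the pooled design; collinear pairs are screened by Pearson
correlation. Because covariates are distances, a NEGATIVE coefficient means
selection FOR the feature (the animal sits closer to it than availability
predicts).

Model validation is individual-blocked k-fold cross-validation: each fold
withholds one animal, trains on the rest, scores the withheld animal's
available points, splits the score range into 10 equal-available-area bins,
and Spearman-correlates the area-adjusted presence frequency per bin against
bin rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .mixed import fit_mixed_logistic
from .synthetic import LandscapeLayers, _raw_distances

__all__ = [
    "CovariateScaler",
    "ResourceSelectionFunction",
    "CVResult",
    "sample_available",
    "distance_covariates",
    "preprocess",
    "build_design",
    "fit_rsf",
    "predict_rsf",
    "area_adjusted_frequencies",
    "blocked_kfold_cv",
]


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def sample_available(polygon, n_presence: int, ratio: int = 10, seed: int = 0) -> np.ndarray:
    """Uniform random points inside a polygon: ``ratio × n_presence`` of them.

    The availability domain is typically the animal's 100% MCP. Sampling is by
    seeded rejection from the bounding box.
    """
    if polygon.is_empty or polygon.area <= 0:
        raise ValueError("availability polygon is degenerate (empty or zero area)")
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    n = ratio * n_presence
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = polygon.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(2 * (n - len(out)), 256)
        xs = rng.uniform(xmin, xmax, m)
        ys = rng.uniform(ymin, ymax, m)
        keep = shapely.contains_xy(polygon, xs, ys)
        out = np.vstack([out, np.column_stack([xs[keep], ys[keep]])])
    return out[:n]


def distance_covariates(
    points, layers: LandscapeLayers, feature_types: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Euclidean distance (m) from each point to the nearest feature of each type.

    Points inside a polygon feature get distance 0. Raises (naming the layer)
    when a referenced layer is empty.
    """
    if isinstance(points, pd.DataFrame):
        xy = points[["x", "y"]].to_numpy(dtype=float)
    else:
        xy = np.asarray(points, dtype=float)
    names = feature_types or tuple(
        f for f in layers.layers if not layers.is_empty(f)
    )
    for name in names:
        if layers.is_empty(name):
            raise ValueError(f"layer {name!r} is empty; distance covariate undefined")
    d = _raw_distances(xy, layers, names)
    return pd.DataFrame(d, columns=[f"dist_{n}" for n in names])


@dataclass(frozen=True)
class CovariateScaler:
    """log(d + 1) then center/scale transform frozen from a training design."""

    means: pd.Series
    sds: pd.Series
    dropped: tuple[str, ...] = ()

    @property
    def covariates(self) -> tuple[str, ...]:
        return tuple(self.means.index)

    def transform(self, raw: pd.DataFrame) -> pd.DataFrame:
        missing = set(self.covariates) - set(raw.columns)
        if missing:
            raise ValueError(f"raw design missing columns {sorted(missing)}")
        v = np.log1p(raw[list(self.covariates)])
        return (v - self.means) / self.sds


def preprocess(
    design: pd.DataFrame,
    covariates: tuple[str, ...] | None = None,
    corr_threshold: float = 0.7,
    drop_priority: tuple[str, ...] = ("dist_ddf",),
) -> tuple[pd.DataFrame, CovariateScaler, pd.DataFrame]:
    """Log-transform, center and scale the distance covariates; screen collinearity.

    Covariates are ``log(d + 1)`` then standardized with the POOLED
    (presence + available) mean and SD. Pairs with |Pearson r| ≥ threshold are
    reported and one member is dropped — the one appearing earliest in
    ``drop_priority``, else the second member of the pair (the coarser layer
    is conventionally listed there). Returns (transformed design, frozen
    scaler, correlation report).
    """
    covs = list(covariates or [c for c in design.columns if c.startswith("dist_")])
    if not covs:
        raise ValueError("no distance covariates in the design")
    v = np.log1p(design[covs])
    sds = v.std(ddof=1)
    if (sds <= 0).any():
        bad = list(sds.index[sds <= 0])
        raise ValueError(f"zero-variance covariates: {bad}")

    corr = v.corr()
    pairs = []
    flagged: set[str] = set()
    remaining = list(covs)
    for i, a in enumerate(covs):
        for b in covs[i + 1 :]:
            r = corr.loc[a, b]
            if abs(r) >= corr_threshold:
                pairs.append((a, b, float(r)))
                if a in remaining and b in remaining:
                    if a in drop_priority and b not in drop_priority:
                        victim = a
                    elif b in drop_priority and a not in drop_priority:
                        victim = b
                    elif a in drop_priority and b in drop_priority:
                        victim = a if drop_priority.index(a) < drop_priority.index(b) else b
                    else:
                        victim = b
                    remaining.remove(victim)
                    flagged.add(victim)
    report = pd.DataFrame(pairs, columns=["covariate_a", "covariate_b", "pearson_r"])

    kept = [c for c in covs if c not in flagged]
    scaler = CovariateScaler(
        means=v[kept].mean(), sds=v[kept].std(ddof=1), dropped=tuple(sorted(flagged))
    )
    out = design.drop(columns=covs).join(scaler.transform(design[covs]))
    return out, scaler, report


def build_design(
    relocations: pd.DataFrame,
    layers: LandscapeLayers,
    feature_types: tuple[str, ...] | None = None,
    availability: pd.DataFrame | None = None,
    ratio: int = 10,
    weight_available: float = 1000.0,
    mcp_percent: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Assemble the raw used–available design for all animals.

    Presence rows come from ``relocations``; available rows either from the
    caller-supplied ``availability`` frame (columns animal_id, x, y) or by
    uniform sampling within each animal's 100% MCP. Rows carry ``case`` (1/0),
    ``weight`` (1 for presence, ``weight_available`` for available) and raw
    ``dist_*`` covariates.
    """
    from .homerange import mcp  # local import to avoid a cycle at module load

    parts = []
    for i, (animal, grp) in enumerate(relocations.groupby("animal_id")):
        pres_xy = grp[["x", "y"]].to_numpy(dtype=float)
        if availability is not None:
            avail_xy = availability.loc[
                availability["animal_id"] == animal, ["x", "y"]
            ].to_numpy(dtype=float)
            if len(avail_xy) == 0:
                raise ValueError(f"no availability rows for animal {animal!r}")
        else:
            poly, _ = mcp(pres_xy, mcp_percent)
            avail_xy = sample_available(poly, len(pres_xy), ratio=ratio, seed=seed + i)
        xy = np.vstack([pres_xy, avail_xy])
        case = np.concatenate([np.ones(len(pres_xy)), np.zeros(len(avail_xy))])
        block = pd.DataFrame({"animal_id": animal, "case": case.astype(int)})
        block["weight"] = np.where(case == 1, 1.0, weight_available)
        block[["x", "y"]] = xy
        parts.append(block)
    design = pd.concat(parts, ignore_index=True)
    dists = distance_covariates(design[["x", "y"]], layers, feature_types)
    return pd.concat([design, dists], axis=1)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class ResourceSelectionFunction(BaseEstimator):
    """Weighted logistic RSF, optionally with individual random effects.

    Parameters
    ----------
    random_effects : "none" for a plain weighted logistic fit (IRLS via GLM);
        "slopes" for a random intercept (fixed variance) plus random slopes
        per covariate, estimated by Laplace-approximated marginal likelihood.
    intercept_variance : the fixed random-intercept variance (default 1e6).

    Fitted attributes: ``coef_`` (Series, one beta per covariate),
    ``intercept_``, ``se_``, ``conf_int_`` (Wald 95%), ``z_``, ``p_``,
    ``random_variances_`` (Series, empty for the fixed-effects fit),
    ``summary_`` (a coefficients frame). Covariates are distances, so negative
    coefficients indicate selection for the feature.
    """

    def __init__(
        self, random_effects: str = "none", intercept_variance: float = 1e6
    ):
        self.random_effects = random_effects
        self.intercept_variance = intercept_variance

    def fit(self, X, y, sample_weight=None, groups=None):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(Xa.shape[1])]
        y = np.asarray(y, dtype=float)
        w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)

        if self.random_effects not in ("none", "slopes", "intercept"):
            raise ValueError("random_effects must be 'none', 'intercept' or 'slopes'")

        if self.random_effects == "none":
            exog = sm.add_constant(Xa)
            glm = sm.GLM(y, exog, family=sm.families.Binomial(), freq_weights=w)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = glm.fit(maxiter=200, tol=1e-10)
            if not res.converged:
                raise RuntimeError("weighted logistic IRLS did not converge")
            beta = res.params
            se = res.bse
            self.random_variances_ = pd.Series(dtype=float)
        else:
            if groups is None:
                raise ValueError("groups (animal ids) required for random effects")
            start = None
            try:
                exog = sm.add_constant(Xa)
                glm = sm.GLM(y, exog, family=sm.families.Binomial(), freq_weights=w)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    start = glm.fit(maxiter=100).params
            except Exception:  # pragma: no cover - start value is a convenience
                start = None
            fit = fit_mixed_logistic(
                Xa, y, w, np.asarray(groups),
                random_slopes=(self.random_effects == "slopes"),
                intercept_variance=self.intercept_variance,
                beta_start=start,
            )
            beta = fit.beta
            se = fit.se
            self.random_variances_ = pd.Series(
                fit.slope_variances,
                index=names[: len(fit.slope_variances)],
                name="variance",
            )
            self.mixed_fit_ = fit

        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.intercept_ = float(beta[0])
        self.intercept_se_ = float(se[0])
        self.coef_ = pd.Series(beta[1:], index=names, name="beta")
        self.se_ = pd.Series(se[1:], index=names, name="se")
        self.z_ = self.coef_ / self.se_
        self.p_ = pd.Series(
            2.0 * stats.norm.sf(np.abs(self.z_)), index=names, name="p"
        )
        self.conf_int_ = pd.DataFrame(
            {
                "lcl": self.coef_ - 1.96 * self.se_,
                "ucl": self.coef_ + 1.96 * self.se_,
            }
        )
        self.summary_ = pd.DataFrame(
            {
                "variable": names,
                "beta": self.coef_.to_numpy(),
                "se": self.se_.to_numpy(),
                "lcl": self.conf_int_["lcl"].to_numpy(),
                "ucl": self.conf_int_["ucl"].to_numpy(),
                "z": self.z_.to_numpy(),
                "p": self.p_.to_numpy(),
            }
        )
        return self

    def decision_function(self, X) -> np.ndarray:
        """Linear predictor x·β (fixed effects, no intercept)."""
        if isinstance(X, pd.DataFrame):
            X = X[list(self.feature_names_in_)].to_numpy(dtype=float)
        return np.asarray(X, dtype=float) @ self.coef_.to_numpy()

    def predict(self, X) -> np.ndarray:
        """Relative selection score exp(x·β); 1 at covariate means (x = 0)."""
        return np.exp(self.decision_function(X))


def fit_rsf(
    design: pd.DataFrame,
    covariates: tuple[str, ...],
    random_effects: str = "slopes",
    intercept_variance: float = 1e6,
) -> ResourceSelectionFunction:
    """Fit an RSF from a preprocessed design frame (thin wrapper over the estimator)."""
    model = ResourceSelectionFunction(
        random_effects=random_effects, intercept_variance=intercept_variance
    )
    return model.fit(
        design[list(covariates)],
        design["case"],
        sample_weight=design["weight"],
        groups=design["animal_id"] if random_effects != "none" else None,
    )


def predict_rsf(model: ResourceSelectionFunction, X) -> np.ndarray:
    """Relative probability of use exp(x·β) for transformed covariates."""
    return model.predict(X)


# ---------------------------------------------------------------------------
# Blocked cross-validation
# ---------------------------------------------------------------------------

def area_adjusted_frequencies(
    scores_available: np.ndarray, scores_presence: np.ndarray, n_bins: int = 10
) -> np.ndarray:
    """Presence frequency per equal-available-area score bin, divided by 1/n_bins.

    Bins are deciles of the withheld animal's available-point scores, so each
    holds the same share of available area; a well-ranked model concentrates
    presence points in the high bins.
    """
    edges = np.quantile(scores_available, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    counts, _ = np.histogram(scores_presence, bins=edges)
    if counts.sum() == 0:
        raise ValueError("no presence points to bin")
    share = counts / counts.sum()
    return share / (1.0 / n_bins)


@dataclass
class CVResult:
    """Blocked cross-validation summary."""

    folds: pd.DataFrame          # animal_id, rho, p, n_presence
    bin_table: pd.DataFrame      # animal_id, bin, area_adjusted_freq
    mean_rho: float
    pooled_rho: float
    pooled_p: float


def blocked_kfold_cv(
    design: pd.DataFrame,
    covariates: tuple[str, ...],
    n_bins: int = 10,
    min_presence: int = 10,
    random_effects: str = "none",
) -> CVResult:
    """Leave-one-animal-out validation with Spearman rank correlation over score bins.

    For each fold the withheld animal's available points define ``n_bins``
    equal-area score bins; the area-adjusted frequency of its presence points
    per bin is correlated (Spearman) against bin rank. Folds whose withheld
    animal has fewer than ``min_presence`` presence points are skipped with a
    warning. Reports per-fold rho, their mean, and a pooled rho over all
    (bin, frequency) pairs.
    """
    animals = design["animal_id"].unique()
    if len(animals) < 2:
        raise ValueError("need >= 2 animals for blocked cross-validation")
    fold_rows = []
    bin_rows = []
    for animal in animals:
        test = design[design["animal_id"] == animal]
        train = design[design["animal_id"] != animal]
        n_pres = int((test["case"] == 1).sum())
        if n_pres < min_presence:
            warnings.warn(
                f"fold {animal!r} skipped: only {n_pres} presence points",
                stacklevel=2,
            )
            continue
        model = fit_rsf(train, covariates, random_effects=random_effects)
        s_avail = model.predict(test.loc[test["case"] == 0, list(covariates)])
        s_pres = model.predict(test.loc[test["case"] == 1, list(covariates)])
        freq = area_adjusted_frequencies(s_avail, s_pres, n_bins)
        rho, p = stats.spearmanr(np.arange(1, n_bins + 1), freq)
        fold_rows.append((animal, float(rho), float(p), n_pres))
        for b, f in enumerate(freq, start=1):
            bin_rows.append((animal, b, float(f)))
    if not fold_rows:
        raise ValueError("all folds skipped; no animal has enough presence points")
    folds = pd.DataFrame(fold_rows, columns=["animal_id", "rho", "p", "n_presence"])
    bins = pd.DataFrame(bin_rows, columns=["animal_id", "bin", "area_adjusted_freq"])
    pooled_rho, pooled_p = stats.spearmanr(bins["bin"], bins["area_adjusted_freq"])
    return CVResult(
        folds=folds,
        bin_table=bins,
        mean_rho=float(folds["rho"].mean()),
        pooled_rho=float(pooled_rho),
        pooled_p=float(pooled_p),
    )
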
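"""Approximate Bayesian computation: priors, reference table, rejection,
model selection, goodness of fit, and regression-adjusted posteriors.

The reference table holds one row per simulation: scenario label, drawn
parameters, and the fixed-order summary statistics of the simulated dataset.
Statistics are standardized by median/MAD over the table; rejection keeps
the ``n_keep`` rows closest to the observed vector in Euclidean distance.
Posterior parameter estimates use Epanechnikov kernel weights on the
retained distances and a weighted local-linear regression adjustment of
each (log-transformed, when strictly positive) parameter on the
standardized statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .coalescent import MODELS, SUMMARY_STAT_NAMES, ScenarioSpec, simulate_dataset, summarize

logger = logging.getLogger(__name__)

PARAM_NAMES = list(ScenarioSpec.PARAM_NAMES)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Per-parameter prior distributions and a uniform model prior.

    Each entry of ``distributions`` maps a parameter name to a tuple:
    ``("uniform", lo, hi)``, ``("loguniform", lo, hi)``, ``("point", v)`` or
    ``("uniform_of", other, lo_frac, hi_frac)`` — a uniform fraction of
    another (already drawn) parameter, used to enforce t2 < t1 by a
    conditional draw.
    """

    distributions: dict[str, tuple]
    models: tuple = MODELS

    def validate(self) -> None:
        for name, dist in self.distributions.items():
            kind = dist[0]
            if kind in ("uniform", "loguniform"):
                lo, hi = dist[1], dist[2]
                if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                    raise ValueError(f"{name}: bounds must be finite and ordered")
                if kind == "loguniform" and lo <= 0:
                    raise ValueError(f"{name}: log-uniform bounds must be positive")
            elif kind == "point":
                pass
            elif kind == "uniform_of":
                if dist[1] not in self.distributions:
                    raise ValueError(f"{name}: unknown reference parameter {dist[1]!r}")
            else:
                raise ValueError(f"{name}: unknown distribution kind {kind!r}")


def default_priors() -> PriorSpec:
    """Default priors: log-uniform Ne in [1e2, 1e6], uniform t1 in [1e3, 1e5],
    t2 conditionally uniform on (0, t1), log-uniform migration in [1e-6, 1e-2]."""
    d = {nm: ("loguniform", 1e2, 1e6)
         for nm in ("ne_anc", "ne_cau_t1", "ne_mor_t1", "ne_cau_t2", "ne_mor_t2")}
    d["t1"] = ("uniform", 1e3, 1e5)
    d["t2"] = ("uniform_of", "t1", 0.0, 1.0)
    d["m1"] = ("loguniform", 1e-6, 1e-2)
    d["m2"] = ("loguniform", 1e-6, 1e-2)
    return PriorSpec(d)


def sample_priors(prior_spec: PriorSpec, n: int, rng) -> pd.DataFrame:
    """Draw *n* i.i.d. parameter vectors honoring the conditional supports."""
    if n < 1:
        raise ValueError("n must be >= 1")
    prior_spec.validate()
    rng = np.random.default_rng(rng)
    cols: dict[str, np.ndarray] = {}
    deferred = []
    for name, dist in prior_spec.distributions.items():
        kind = dist[0]
        if kind == "uniform":
            cols[name] = rng.uniform(dist[1], dist[2], size=n)
        elif kind == "loguniform":
            cols[name] = np.exp(rng.uniform(np.log(dist[1]), np.log(dist[2]), size=n))
        elif kind == "point":
            cols[name] = np.full(n, float(dist[1]))
        else:
            deferred.append((name, dist))
    for name, dist in deferred:
        _, other, lo, hi = dist
        cols[name] = cols[other] * rng.uniform(lo, hi, size=n)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# reference table
# ---------------------------------------------------------------------------

def run_reference_table(prior_spec: PriorSpec, n_sim: int, seed: int,
                        base_spec: ScenarioSpec | None = None,
                        out_path=None, chunk_size: int = 1000) -> pd.DataFrame:
    """Simulate the ABC reference table: (model, parameters, summary stats).

    Models are assigned uniformly at random.  Per-row randomness derives from
    ``SeedSequence(seed, row)``, so the table is reproducible and resumable:
    if *out_path* exists, completed rows are kept and simulation continues
    from the next row index.  A failing draw is skipped and logged, never
    imputed.
    """
    if base_spec is None:
        base_spec = ScenarioSpec("SI", 1e3, 1e3, 1e3, 1e3, 1e3, 0, 0, 2e4, 1e4)
    columns = ["model"] + PARAM_NAMES + SUMMARY_STAT_NAMES
    start = 0
    existing = None
    if out_path is not None:
        import os

        if os.path.exists(out_path):
            existing = pd.read_csv(out_path, sep="\t")
            start = len(existing)
    chunks = [] if existing is None else [existing]
    buf = []
    for i in range(start, n_sim):
        row_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        model = prior_spec.models[int(row_rng.integers(len(prior_spec.models)))]
        params = sample_priors(prior_spec, 1, row_rng).iloc[0].to_dict()
        if model == "SI":
            params["m1"] = params["m2"] = 0.0
        spec = base_spec.with_params(model=model, **{k: params[k] for k in PARAM_NAMES})
        try:
            stats = summarize(simulate_dataset(spec, row_rng))
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("simulation %d failed (%s); row skipped", i, exc)
            continue
        if not np.all(np.isfinite(stats)):
            logger.warning("simulation %d produced non-finite statistics; row skipped", i)
            continue
        buf.append([model] + [params[k] for k in PARAM_NAMES] + list(stats))
        if len(buf) >= chunk_size:
            chunks.append(pd.DataFrame(buf, columns=columns))
            buf = []
            if out_path is not None:
                pd.concat(chunks, ignore_index=True).to_csv(out_path, sep="\t", index=False)
    if buf:
        chunks.append(pd.DataFrame(buf, columns=columns))
    table = pd.concat(chunks, ignore_index=True) if chunks else pd.DataFrame(columns=columns)
    if out_path is not None:
        table.to_csv(out_path, sep="\t", index=False)
    return table


# ---------------------------------------------------------------------------
# rejection
# ---------------------------------------------------------------------------

@dataclass
class RejectionResult:
    """Retained simulations with distances and the standardization used."""

    retained: pd.DataFrame  # includes a "distance" column
    stat_cols: list[str]
    center: np.ndarray  # per-stat median over the table
    scale: np.ndarray  # per-stat MAD over the table
    observed: np.ndarray  # raw observed statistics (stat_cols order)

    @property
    def distances(self) -> np.ndarray:
        return self.retained["distance"].to_numpy()

    def standardized(self, frame_or_vector):
        arr = np.asarray(frame_or_vector[self.stat_cols] if isinstance(
            frame_or_vector, pd.DataFrame) else frame_or_vector, dtype=float)
        return (arr - self.center) / self.scale

    def weights(self) -> np.ndarray:
        """Epanechnikov weights with bandwidth = max retained distance."""
        d = self.distances
        h = d.max()
        if h == 0:
            return np.ones_like(d)
        w = 1.0 - (d / h) ** 2
        w[w <= 0] = np.finfo(float).tiny
        return w


def reject(table: pd.DataFrame, observed_stats, n_keep: int,
           stat_cols: list[str] | None = None) -> RejectionResult:
    """Keep the *n_keep* simulations closest to the observed statistics.

    Statistics are standardized by median/MAD over the table; columns with
    MAD = 0 are dropped with a warning.  Distance is Euclidean; ties are
    broken by row order (stable sort).
    """
    if stat_cols is None:
        stat_cols = [c for c in SUMMARY_STAT_NAMES if c in table.columns]
    if n_keep > len(table):
        raise ValueError(f"n_keep={n_keep} exceeds table size {len(table)}")
    obs = np.asarray(
        observed_stats[stat_cols] if isinstance(observed_stats, pd.Series)
        else observed_stats, dtype=float)
    X = table[stat_cols].to_numpy(float)
    center = np.median(X, axis=0)
    mad = np.median(np.abs(X - center), axis=0)
    keep_cols = mad > 0
    if not keep_cols.all():
        dropped = [c for c, k in zip(stat_cols, keep_cols) if not k]
        warnings.warn(f"statistics with MAD=0 dropped: {dropped}")
    stat_cols = [c for c, k in zip(stat_cols, keep_cols) if k]
    X = X[:, keep_cols]
    center, mad = center[keep_cols], mad[keep_cols]
    obs = obs[keep_cols]
    Z = (X - center) / mad
    z_obs = (obs - center) / mad
    d = np.sqrt(((Z - z_obs) ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")[:n_keep]
    retained = table.iloc[order].copy()
    retained["distance"] = d[order]
    return RejectionResult(retained, stat_cols, center, mad, obs)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

_PP_EPS = 1e-4


def model_posterior(rej: RejectionResult, method: str = "mnlogistic",
                    models: tuple | None = None, seed: int = 0) -> dict:
    """Model posterior probabilities and pairwise Bayes factors.

    ``method="rejection"`` uses retained-set model frequencies;
    ``"mnlogistic"`` fits a weighted multinomial logistic regression of the
    model label on the standardized statistics over the retained set and
    evaluates it at the observed vector; ``"neuralnet"`` is a single-hidden-
    layer classifier variant.  PPs are clipped away from 0 and renormalized
    before Bayes factors (ratios of PPs, valid under the uniform model
    prior).
    """
    retained = rej.retained
    if models is None:
        models = tuple(dict.fromkeys(retained["model"]))
    if len(models) < 2:
        raise ValueError("model selection needs >= 2 models")
    labels = retained["model"].to_numpy()
    present = [m for m in models if (labels == m).any()]
    absent = [m for m in models if m not in present]
    if absent:
        warnings.warn(f"models absent from retained set get PP=0: {absent}")

    if method == "rejection":
        pp = pd.Series({m: float((labels == m).mean()) for m in models})
    elif method in ("mnlogistic", "neuralnet"):
        Z = rej.standardized(retained)
        z_obs = rej.standardized(rej.observed)
        w = rej.weights()
        if len(present) < 2:
            pp = pd.Series({m: 1.0 if m in present else 0.0 for m in models})
        elif method == "mnlogistic":
            from sklearn.linear_model import LogisticRegression

            clf = LogisticRegression(max_iter=2000, C=1e3)
            clf.fit(Z, labels, sample_weight=w)
            proba = clf.predict_proba(z_obs.reshape(1, -1))[0]
            pp = pd.Series(dict(zip(clf.classes_, proba))).reindex(models).fillna(0.0)
        else:
            from sklearn.neural_network import MLPClassifier

            clf = MLPClassifier(hidden_layer_sizes=(8,), max_iter=2000,
                                random_state=seed)
            clf.fit(Z, labels)
            proba = clf.predict_proba(z_obs.reshape(1, -1))[0]
            pp = pd.Series(dict(zip(clf.classes_, proba))).reindex(models).fillna(0.0)
    else:
        raise ValueError(f"unknown method {method!r}")

    pp = pp / pp.sum()
    clipped = pp.clip(lower=_PP_EPS)
    clipped = clipped / clipped.sum()
    bf = pd.DataFrame(
        np.outer(clipped.to_numpy(), 1.0 / clipped.to_numpy()),
        index=list(models), columns=list(models),
    )
    return {"pp": pp, "bayes_factors": bf, "method": method}


def bayes_factor(pp_i: float, pp_j: float) -> float:
    """Bayes factor between two models under the uniform model prior."""
    return pp_i / pp_j


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

def goodness_of_fit(model_table: pd.DataFrame, observed_stats, n_rep: int = 1000,
                    rng=None, stat_cols: list[str] | None = None) -> float:
    """Marginal-density goodness-of-fit p-value for one model.

    The test statistic is the Euclidean distance (median/MAD standardized
    over the model's simulations) from a statistic vector to the mean
    simulated vector; p is the smoothed proportion of simulated datasets
    whose distance exceeds the observed one.
    """
    if n_rep < 100:
        warnings.warn("n_rep < 100 gives a coarse p-value resolution")
    rng = np.random.default_rng(rng)
    if stat_cols is None:
        stat_cols = [c for c in SUMMARY_STAT_NAMES if c in model_table.columns]
    X = model_table[stat_cols].to_numpy(float)
    obs = np.asarray(
        observed_stats[stat_cols] if isinstance(observed_stats, pd.Series)
        else observed_stats, dtype=float)
    center = np.median(X, axis=0)
    mad = np.median(np.abs(X - center), axis=0)
    keep = mad > 0
    X, obs, center, mad = X[:, keep], obs[keep], center[keep], mad[keep]
    Z = (X - center) / mad
    z_obs = (obs - center) / mad
    ref = Z.mean(axis=0)
    if len(Z) > n_rep:
        Z = Z[rng.choice(len(Z), size=n_rep, replace=False)]
    d_null = np.sqrt(((Z - ref) ** 2).sum(axis=1))
    d_obs = float(np.sqrt(((z_obs - ref) ** 2).sum()))
    return float(((d_null > d_obs).sum() + 1) / (len(d_null) + 1))


# ---------------------------------------------------------------------------
# posterior parameter estimation
# ---------------------------------------------------------------------------

def weighted_quantile(values, q, weights) -> np.ndarray:
    """Weighted empirical quantiles (inverse of the weighted ECDF)."""
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    cw /= cw[-1]
    return np.interp(np.atleast_1d(q), cw, v)


def weighted_mode(values, weights) -> float:
    """Mode of a weighted kernel density estimate over the sample range."""
    values = np.asarray(values, float)
    if np.ptp(values) == 0:
        return float(values[0])
    try:
        kde = gaussian_kde(values, weights=weights)
    except np.linalg.LinAlgError:
        return float(weighted_quantile(values, 0.5, weights)[0])
    grid = np.linspace(values.min(), values.max(), 512)
    return float(grid[np.argmax(kde(grid))])


@dataclass
class PosteriorEstimate:
    """Per-parameter posterior summaries plus the adjusted retained sample."""

    summary: pd.DataFrame  # index parameter; columns mode, q025, q975
    adjusted: pd.DataFrame  # regression-adjusted parameter values
    weights: np.ndarray
    adjusted_flag: bool = True


def estimate_posteriors(rej: RejectionResult, params: list[str] | None = None,
                        adjust: bool = True) -> PosteriorEstimate:
    """Weighted, regression-adjusted posterior summaries for each parameter.

    Strictly positive parameters are log-transformed before the local-linear
    adjustment and back-transformed after.  The mode is the argmax of a
    weighted kernel density (computed on the transformed scale); the 2.5%
    and 97.5% bounds are weighted empirical quantiles.  A singular
    regression design falls back to unadjusted weighted quantiles with a
    warning.
    """
    retained = rej.retained
    if params is None:
        params = [p for p in PARAM_NAMES if p in retained.columns]
    w = rej.weights()
    Z = rej.standardized(retained)
    z_obs = rej.standardized(rej.observed)
    X = Z - z_obs  # adjust to the observed point
    design = np.column_stack([np.ones(len(X)), X])
    sw = np.sqrt(w)
    rows = {}
    adjusted = {}
    did_adjust = adjust
    for p in params:
        y = retained[p].to_numpy(float)
        positive = (y > 0).all()
        ty = np.log(y) if positive else y
        t_adj = ty
        if adjust:
            # min-norm solution tolerates exactly collinear statistics (their
            # linear dependence holds for the observed vector too, so the
            # prediction is unaffected); only a degenerate design falls back
            beta, _, rank, _ = np.linalg.lstsq(design * sw[:, None], ty * sw, rcond=None)
            if rank < 2:
                warnings.warn(f"singular regression design for {p!r}; "
                              "using unadjusted weighted quantiles")
                did_adjust = False
            else:
                t_adj = ty - X @ beta[1:]
        vals = np.exp(t_adj) if positive else t_adj
        adjusted[p] = vals
        mode_t = weighted_mode(t_adj, w)
        q = weighted_quantile(vals, [0.025, 0.975], w)
        mode = float(np.exp(mode_t)) if positive else float(mode_t)
        mode = float(np.clip(mode, q[0], q[1]))
        rows[p] = dict(mode=mode, q025=float(q[0]), q975=float(q[1]))
    return PosteriorEstimate(
        pd.DataFrame(rows).T[["mode", "q025", "q975"]],
        pd.DataFrame(adjusted, index=retained.index),
        w, did_adjust,
    )


def generations_to_years(t_generations: float, years_per_generation: float = 5.0) -> dict:
    """Convert a time in generations to years and kyr (nearest thousand)."""
    if t_generations < 0 or years_per_generation <= 0:
        raise ValueError("need t_generations >= 0 and years_per_generation > 0")
    years = float(t_generations) * float(years_per_generation)
    return {"years": years, "kyr": round(years / 1000.0)}
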
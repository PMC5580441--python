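"""Approximate Bayesian Computation: model choice and parameter estimation.

The machinery follows the standard rejection-ABC toolkit: summary
statistics are scaled by their median absolute deviation across the
reference table, the closest ``tolerance`` fraction of simulations is
retained, retained draws get Epanechnikov weights in distance, model
posterior probabilities come from a weighted multinomial logistic
regression of model labels on statistics evaluated at the observation,
and parameter posteriors are summarised from the (optionally
regression-adjusted) retained draws with weighted quantiles and a
weighted-KDE mode.

Parameter draws are logit-transformed to an open scale using their uniform
prior bounds before any regression adjustment and back-transformed after,
which guarantees adjusted draws respect the prior support.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, median_abs_deviation
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPRegressor

from .errors import ABCError

SUMMARY_ROWS = (
    "Minimum",
    "Weighted 2.5%",
    "Weighted Median",
    "Weighted Mean",
    "Weighted Mode",
    "Weighted 97.5%",
    "Maximum",
)


@dataclass
class ReferenceTable:
    """(parameters, statistics) pairs simulated from one model's prior."""

    model_code: str
    params: pd.DataFrame
    stats: np.ndarray
    stat_names: list[str]
    param_bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        self.stats = np.asarray(self.stats, dtype=float)
        if self.stats.shape != (len(self.params), len(self.stat_names)):
            raise ABCError("stats shape does not match params/stat_names")
        if not np.all(np.isfinite(self.stats)):
            raise ABCError("reference table contains non-finite statistics")

    @property
    def n(self) -> int:
        return len(self.params)

    def to_csv(self, path) -> None:
        frame = self.params.copy()
        frame.insert(0, "model", self.model_code)
        for i, name in enumerate(self.stat_names):
            frame[name] = self.stats[:, i]
        frame.to_csv(path, index=False)


def _mad_scales(stats: np.ndarray, stat_names: list[str]) -> np.ndarray:
    """Per-statistic MAD (normal-consistent), SD fallback, 0 = drop column."""
    scales = median_abs_deviation(stats, axis=0, scale="normal")
    for j in np.flatnonzero(scales == 0.0):
        sd = float(stats[:, j].std())
        if sd > 0:
            scales[j] = sd
        else:
            warnings.warn(
                f"statistic {stat_names[j]!r} is constant across the table; "
                "dropped from the distance",
                stacklevel=2,
            )
    return scales


def normalize_and_distance(
    obs: np.ndarray, stats: np.ndarray, stat_names: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean distance of every table row to the observation.

    Each statistic is divided by its median absolute deviation across the
    table (SD fallback; constant statistics are dropped with a warning).
    Returns (distances, scales).
    """
    obs = np.asarray(obs, dtype=float).ravel()
    if obs.size != stats.shape[1]:
        raise ABCError(
            f"observed vector has {obs.size} statistics, table has "
            f"{stats.shape[1]}"
        )
    scales = _mad_scales(stats, stat_names)
    keep = scales > 0
    z = (stats[:, keep] - obs[keep]) / scales[keep]
    return np.sqrt((z**2).sum(axis=1)), scales


def rejection_sample(
    distances: np.ndarray, tolerance: float
) -> tuple[np.ndarray, np.ndarray]:
    """Retain the closest ``ceil(tolerance * N)`` rows with Epanechnikov weights.

    Ties at the acceptance boundary are broken by row index (stable sort),
    so retention is deterministic. Weights are ``1 - (d / delta)^2`` with
    delta the largest retained distance; when all retained distances are
    zero every weight is 1.
    """
    if not 0.0 < tolerance <= 1.0:
        raise ABCError(f"tolerance must be in (0, 1], got {tolerance}")
    n_keep = int(np.ceil(tolerance * distances.size))
    order = np.argsort(distances, kind="stable")
    idx = order[:n_keep]
    delta = distances[idx].max()
    if delta == 0.0:
        weights = np.ones(n_keep)
    else:
        weights = 1.0 - (distances[idx] / delta) ** 2
        if weights.sum() == 0.0:
            weights = np.ones(n_keep)
    return idx, weights


def bayes_factors(posteriors: dict[str, float]) -> pd.DataFrame:
    """BF_ij = p_i / p_j under equal model priors (inf where p_j = 0)."""
    codes = list(posteriors)
    p = np.array([posteriors[c] for c in codes], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        bf = p[:, None] / p[None, :]
    bf[np.isnan(bf)] = 1.0  # 0/0: no evidence either way
    return pd.DataFrame(bf, index=codes, columns=codes)


def _pooled_retention(
    obs: np.ndarray, tables: dict[str, ReferenceTable], tolerance: float
):
    codes = list(tables)
    first = tables[codes[0]]
    stat_names = first.stat_names
    for t in tables.values():
        if t.stat_names != stat_names:
            raise ABCError("reference tables disagree on statistic ordering")
    stats = np.vstack([tables[c].stats for c in codes])
    labels = np.concatenate(
        [np.full(tables[c].n, i) for i, c in enumerate(codes)]
    )
    distances, _ = normalize_and_distance(obs, stats, stat_names)
    idx, weights = rejection_sample(distances, tolerance)
    return codes, stats, labels, idx, weights


def model_posterior_mnlogistic(
    obs: np.ndarray,
    tables: dict[str, ReferenceTable],
    tolerance: float,
    regularization: float = 100.0,
) -> dict[str, float]:
    """Posterior model probabilities by multinomial logistic regression.

    Rows of all models are pooled, the closest ``tolerance`` fraction is
    retained, and a weighted (Epanechnikov) multinomial logistic regression
    of model label on standardised statistics is evaluated at the observed
    vector. ``regularization`` is the inverse L2 strength (mild by default,
    to keep perfectly separable tables finite). A model with no retained
    rows gets probability 0 with a warning.
    """
    if len(tables) < 2:
        raise ABCError("model choice needs >=2 models")
    obs = np.asarray(obs, dtype=float).ravel()
    codes, stats, labels, idx, weights = _pooled_retention(obs, tables, tolerance)
    kept_labels = labels[idx]
    present = np.unique(kept_labels)
    missing = [codes[i] for i in range(len(codes)) if i not in present]
    if missing:
        warnings.warn(
            f"models {missing} have no retained simulations; probability 0",
            stacklevel=2,
        )
    if present.size == 1:
        return {c: (1.0 if codes.index(c) in present else 0.0) for c in codes}
    x = stats[idx]
    centre, spread = x.mean(axis=0), x.std(axis=0)
    spread[spread == 0.0] = 1.0
    xz = (x - centre) / spread
    oz = ((obs - centre) / spread).reshape(1, -1)
    clf = LogisticRegression(C=regularization, max_iter=2000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(xz, kept_labels, sample_weight=np.maximum(weights, 1e-12))
    probs = clf.predict_proba(oz)[0]
    out = {c: 0.0 for c in codes}
    for cls, pr in zip(clf.classes_, probs):
        out[codes[int(cls)]] = float(pr)
    total = sum(out.values())
    return {c: v / total for c, v in out.items()}


def cross_validate_model_choice(
    tables: dict[str, ReferenceTable],
    tolerance: float,
    n_pseudo: int,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leave-one-out misclassification check for the model-choice step.

    For each model, ``n_pseudo`` table rows are treated as pseudo-observed
    datasets, removed from their table, and classified against the rest.
    Returns (confusion, mean_posterior): hard argmax counts and the soft
    mean posterior probability matrix, rows = true model.
    """
    if n_pseudo < 1:
        raise ABCError("n_pseudo must be >= 1")
    codes = list(tables)
    confusion = pd.DataFrame(0, index=codes, columns=codes, dtype=int)
    soft = pd.DataFrame(0.0, index=codes, columns=codes)
    for true_code in codes:
        table = tables[true_code]
        picks = rng.choice(table.n, size=n_pseudo, replace=False)
        for row in picks:
            pseudo = table.stats[row]
            mask = np.ones(table.n, dtype=bool)
            mask[row] = False
            reduced = dict(tables)
            reduced[true_code] = ReferenceTable(
                true_code,
                table.params.iloc[mask].reset_index(drop=True),
                table.stats[mask],
                table.stat_names,
                table.param_bounds,
            )
            post = model_posterior_mnlogistic(pseudo, reduced, tolerance)
            best = max(post, key=post.get)
            confusion.loc[true_code, best] += 1
            for c in codes:
                soft.loc[true_code, c] += post[c]
    return confusion, soft / n_pseudo


def goodness_of_fit(
    obs: np.ndarray,
    table: ReferenceTable,
    tolerance: float,
    n_null: int,
    rng: np.random.Generator,
) -> tuple[float, np.ndarray]:
    """Prior goodness-of-fit test for one model.

    Test statistic: the median normalised distance from the observation to
    its retained set. The null distribution re-applies the identical
    procedure to ``n_null`` rows drawn from the table (each excluded from
    its own retained set); p is the fraction of null statistics at least as
    large as the observed one.
    """
    if n_null < 100:
        raise ABCError("n_null must be >= 100")
    obs = np.asarray(obs, dtype=float).ravel()

    def _stat(target: np.ndarray, stats: np.ndarray) -> float:
        d, _ = normalize_and_distance(target, stats, table.stat_names)
        idx, _w = rejection_sample(d, tolerance)
        return float(np.median(d[idx]))

    observed_stat = _stat(obs, table.stats)
    null = np.empty(n_null)
    picks = rng.choice(table.n, size=n_null, replace=n_null > table.n)
    mask = np.ones(table.n, dtype=bool)
    for i, row in enumerate(picks):
        mask[row] = False
        null[i] = _stat(table.stats[row], table.stats[mask])
        mask[row] = True
    p = float((null >= observed_stat).mean())
    return p, null


@dataclass
class PosteriorResult:
    """Retained draws, weights and Table-style weighted summaries."""

    model_code: str
    retained_index: np.ndarray
    distances: np.ndarray
    weights: np.ndarray
    adjusted: pd.DataFrame
    method: str
    summaries: pd.DataFrame  # rows = SUMMARY_ROWS, columns = parameters

    def interval(self, param: str, level: float = 0.95) -> tuple[float, float]:
        lo = (1.0 - level) / 2.0
        vals = self.adjusted[param].to_numpy()
        return (
            _weighted_quantile(vals, self.weights, lo),
            _weighted_quantile(vals, self.weights, 1.0 - lo),
        )

    def to_csv(self, path) -> None:
        self.summaries.to_csv(path)


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(np.interp(q * cum[-1], cum, v))


def _weighted_mode(values: np.ndarray, weights: np.ndarray) -> float:
    if np.ptp(values) == 0.0:
        return float(values[0])
    kde = gaussian_kde(values, bw_method="silverman", weights=weights)
    grid = np.linspace(values.min(), values.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def _summarise(adjusted: pd.DataFrame, weights: np.ndarray) -> pd.DataFrame:
    out = {}
    for name in adjusted.columns:
        vals = adjusted[name].to_numpy()
        out[name] = [
            float(vals.min()),
            _weighted_quantile(vals, weights, 0.025),
            _weighted_quantile(vals, weights, 0.5),
            float(np.average(vals, weights=weights)),
            _weighted_mode(vals, weights),
            _weighted_quantile(vals, weights, 0.975),
            float(vals.max()),
        ]
    return pd.DataFrame(out, index=list(SUMMARY_ROWS))


def _logit_transform(
    params: pd.DataFrame, bounds: dict[str, tuple[float, float]]
) -> np.ndarray:
    cols = []
    for name in params.columns:
        a, b = bounds[name]
        u = (params[name].to_numpy() - a) / (b - a)
        u = np.clip(u, 1e-12, 1.0 - 1e-12)
        cols.append(np.log(u / (1.0 - u)))
    return np.column_stack(cols)


def _logit_back(theta: np.ndarray, names, bounds) -> pd.DataFrame:
    out = {}
    for j, name in enumerate(names):
        a, b = bounds[name]
        u = 1.0 / (1.0 + np.exp(-theta[:, j]))
        out[name] = a + (b - a) * u
    return pd.DataFrame(out)


def estimate_parameters(
    obs: np.ndarray,
    table: ReferenceTable,
    tolerance: float,
    method: str = "loclinear",
    rng: np.random.Generator | None = None,
    nnet_hidden: int = 5,
    nnet_decay: float = 0.01,
    nnet_restarts: int = 10,
) -> PosteriorResult:
    """ABC posterior for one model's parameters.

    ``method``:

    * ``rejection`` — weighted retained draws, no adjustment.
    * ``loclinear`` — local-linear regression adjustment: a weighted linear
      fit of each (logit-transformed) parameter on the normalised
      statistics, with draws shifted to the observed vector. Deterministic
      given the table; the default.
    * ``neuralnet`` — single-hidden-layer (``nnet_hidden`` units,
      ``nnet_decay`` L2) regression adjustment; ``nnet_restarts`` restarts
      aggregated by median, seeded from ``rng``.

    Degenerate regressions (collinear statistics) fall back to rejection
    with a warning. Summaries use Epanechnikov weights throughout.
    """
    if method not in ("rejection", "loclinear", "neuralnet"):
        raise ABCError(f"unknown method {method!r}")
    obs = np.asarray(obs, dtype=float).ravel()
    distances, scales = normalize_and_distance(
        obs, table.stats, table.stat_names
    )
    idx, weights = rejection_sample(distances, tolerance)
    keep = scales > 0
    x = (table.stats[idx][:, keep] - obs[keep]) / scales[keep]
    theta = _logit_transform(table.params.iloc[idx], table.param_bounds)
    names = list(table.params.columns)

    adjusted_theta = theta
    if method == "loclinear":
        design = np.column_stack([np.ones(x.shape[0]), x])
        wsqrt = np.sqrt(weights)
        try:
            coef, _res, rank, _sv = np.linalg.lstsq(
                design * wsqrt[:, None], theta * wsqrt[:, None], rcond=None
            )
            if rank < design.shape[1]:
                raise np.linalg.LinAlgError("rank-deficient design")
            adjusted_theta = theta - x @ coef[1:]
        except np.linalg.LinAlgError:
            warnings.warn(
                "degenerate local-linear regression; falling back to rejection",
                stacklevel=2,
            )
            method = "rejection"
    elif method == "neuralnet":
        if rng is None:
            rng = np.random.default_rng(0)
        preds = []
        for _ in range(nnet_restarts):
            net = MLPRegressor(
                hidden_layer_sizes=(nnet_hidden,),
                alpha=nnet_decay,
                max_iter=500,
                random_state=int(rng.integers(2**31 - 1)),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                net.fit(x, theta)
            fitted = net.predict(x).reshape(theta.shape)
            at_obs = net.predict(np.zeros((1, x.shape[1]))).reshape(1, -1)
            preds.append(theta - fitted + at_obs)
        adjusted_theta = np.median(np.stack(preds), axis=0)

    adjusted = _logit_back(adjusted_theta, names, table.param_bounds)
    return PosteriorResult(
        model_code=table.model_code,
        retained_index=idx,
        distances=distances[idx],
        weights=weights,
        adjusted=adjusted,
        method=method,
        summaries=_summarise(adjusted, weights),
    )


def posterior_predictive_check(
    posterior: PosteriorResult,
    obs: np.ndarray,
    simulate,
    n_rep: int,
    rng: np.random.Generator,
) -> pd.Series:
    """Tail probability of each observed statistic under the posterior.

    ``simulate(params: dict, rng) -> StatVector-like`` re-simulates one
    dataset; parameters are resampled from the weighted retained draws.
    Returns, per statistic, the fraction of replicates >= the observation.
    """
    obs = np.asarray(obs, dtype=float).ravel()
    w = posterior.weights / posterior.weights.sum()
    reps = np.empty((n_rep, obs.size))
    names = None
    for r in range(n_rep):
        row = int(rng.choice(posterior.adjusted.shape[0], p=w))
        params = posterior.adjusted.iloc[row].to_dict()
        sv = simulate(params, rng)
        vals = np.asarray(getattr(sv, "values", sv), dtype=float).ravel()
        names = getattr(sv, "names", names)
        reps[r] = vals
    tails = (reps >= obs).mean(axis=0)
    index = names if names is not None else range(obs.size)
    return pd.Series(tails, index=index)
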
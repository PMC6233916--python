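"""Pairwise density-ratio differential-network classification (JDINAC).

The model assumes that the difference between outcome classes arises from the
collective effect of differential *pairwise* dependencies between features.
For every component pair (i, j) the class-conditional joint density of the
two log(ISU+1) values is estimated by a bivariate Gaussian product-kernel
KDE, and the per-participant feature is the log density ratio

    r_ij(x) = ln [ f1_ij(x_i, x_j) / f0_ij(x_i, x_j) ],

entered into an L1-penalised, class-weighted logistic regression

    logit P(Y=1 | x) = a0 + sum_{i<j} b_ij * r_ij(x),  sum |b_ij| <= c.

Estimation uses multiple stratified half-splitting: densities are estimated
on one half, the sparse logistic model on the other, then the halves swap;
repeated T times with fresh splits.  Out-of-sample predictions (for the
density half, whose participants the logistic fit never saw) are averaged
over repetitions.  A pair's *differential weight* is the number of fitted
models in which its coefficient is nonzero; pairs selected in at least a
fraction (default 25%) of models form the differential network, with the
sign of the mean nonzero coefficient giving the direction (risk/protective).

Kernel evaluation on the density-training half itself uses leave-one-out
sums, so a participant's own kernel mass never inflates their class-1 (or
class-0) density — without this the averaged "out-of-sample" predictions
would leak the participant's label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from scipy.stats import norm, rankdata

from ._l1 import L1LogisticFit, fit_l1_logistic_cv
from .cohort_io import CRDMatrix

logger = logging.getLogger(__name__)

#: Density floor applied before taking logs; keeps features finite at the
#: edges of the empirical support (and exactly 0 when both classes floor).
DENSITY_FLOOR = 1e-10

#: Minimum class size on the density-training half.
MIN_DENSITY_POINTS = 5


@dataclass
class NormalScoresTransform:
    """Per-component rank-to-normal-scores map, frozen on the training data.

    The pair log density ratio is invariant (in population) to monotone
    per-component transforms — the Jacobian cancels between numerator and
    denominator — so the KDE stage is free to work on the scale where a
    fixed-bandwidth Gaussian kernel performs best.  Normal scores
    (``Phi^-1(rank / (n+1))``) remove marginal skew entirely; ties (e.g. the
    zero spike of below-detection responses) share their group's average
    rank.  New data is mapped through the stored training quantiles by
    linear interpolation, clamped to the training range.
    """

    grids: list[np.ndarray]     # per component: unique training values
    scores: list[np.ndarray]    # per component: mean normal score per value

    @classmethod
    def fit(cls, x: np.ndarray) -> "NormalScoresTransform":
        n = x.shape[0]
        grids, scores = [], []
        for c in range(x.shape[1]):
            col = x[:, c]
            s = norm.ppf(rankdata(col, method="average") / (n + 1))
            uniq, inverse = np.unique(col, return_inverse=True)
            mean_s = np.bincount(inverse, weights=s) / np.bincount(inverse)
            grids.append(uniq)
            scores.append(mean_s)
        return cls(grids=grids, scores=scores)

    def apply(self, x: np.ndarray) -> np.ndarray:
        out = np.empty_like(x, dtype=float)
        for c in range(x.shape[1]):
            out[:, c] = np.interp(x[:, c], self.grids[c], self.scores[c])
        return out


def pair_list(p: int) -> list[tuple[int, int]]:
    """Lexicographic (i, j), i < j, over p components."""
    return [(i, j) for i in range(p) for j in range(i + 1, p)]


def bandwidths(points: np.ndarray, rule: str = "scott", fixed: float | None = None) -> np.ndarray:
    """Per-dimension kernel bandwidths for a bivariate product-kernel KDE.

    ``scott``: sigma * n^(-1/(d+4)) with d=2; ``silverman``:
    sigma * (4 / (d+2))^(1/(d+4)) * n^(-1/(d+4)) (identical to Scott at d=2);
    ``fixed``: the supplied constant for every dimension.  Bandwidths are
    floored at 1e-3 so near-constant dimensions (frequent with zero-inflated
    data) stay numerically usable.
    """
    n, d = points.shape[0], 2
    sigma = points.std(axis=0, ddof=1) if n > 1 else np.zeros(points.shape[1])
    if rule == "scott":
        h = sigma * n ** (-1.0 / (d + 4))
    elif rule == "silverman":
        h = sigma * (4.0 / (d + 2)) ** (1.0 / (d + 4)) * n ** (-1.0 / (d + 4))
    elif rule == "fixed":
        if fixed is None or fixed <= 0:
            raise ValueError("fixed bandwidth rule needs a positive value")
        h = np.full(points.shape[1], float(fixed))
    else:
        raise ValueError(f"unknown bandwidth rule {rule!r}")
    return np.maximum(h, 1e-3)


@dataclass
class BivariateKDE:
    """Gaussian product-kernel density over one component pair."""

    points: np.ndarray          # (n, 2)
    h: np.ndarray               # (2,)

    def evaluate(self, queries: np.ndarray, floor: float = DENSITY_FLOOR) -> np.ndarray:
        q = np.atleast_2d(queries)
        k1 = np.exp(-0.5 * ((q[:, [0]] - self.points[None, :, 0].reshape(1, -1)) / self.h[0]) ** 2)
        k2 = np.exp(-0.5 * ((q[:, [1]] - self.points[None, :, 1].reshape(1, -1)) / self.h[1]) ** 2)
        dens = (k1 * k2).mean(axis=1) / (self.h[0] * self.h[1] * 2.0 * np.pi)
        return np.maximum(dens, floor)


def fit_pair_density(points: np.ndarray, bandwidth_rule: str = "scott",
                     fixed_bandwidth: float | None = None,
                     label: str = "") -> BivariateKDE:
    """KDE for one component pair and class; needs >= 5 points."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("expected an (n, 2) matrix of pair values")
    if points.shape[0] < MIN_DENSITY_POINTS:
        raise ValueError(
            f"too few points ({points.shape[0]} < {MIN_DENSITY_POINTS}) to fit "
            f"the pair density{f' for {label}' if label else ''}"
        )
    return BivariateKDE(points=points.copy(), h=bandwidths(points, bandwidth_rule, fixed_bandwidth))


@dataclass
class PairDensityModel:
    """Class-conditional KDEs over all component pairs, stored compactly.

    The Gaussian product kernel shares one bandwidth per component (per
    class), so the model keeps the class training matrices and the two
    bandwidth vectors instead of p(p-1)/2 separate KDE objects.
    """

    component_ids: list
    train: dict[int, np.ndarray]        # class -> (n_y, p) log1 values
    h: dict[int, np.ndarray]            # class -> (p,) bandwidths

    def pair_kde(self, i: int, j: int, cls: int) -> BivariateKDE:
        return BivariateKDE(points=self.train[cls][:, [i, j]], h=self.h[cls][[i, j]])


def fit_pair_density_model(
    x: np.ndarray, y: np.ndarray, component_ids: list,
    bandwidth_rule: str = "scott", fixed_bandwidth: float | None = None,
    pooled_bandwidth: bool = True,
) -> PairDensityModel:
    """Class-conditional KDEs with per-component bandwidths.

    By default one bandwidth per component is computed on the pooled density
    half and shared by both classes: the log *ratio* of two KDEs smoothed
    with different bandwidths is biased away from zero even when the class
    densities are identical, so sharing the bandwidth cancels that bias.
    ``pooled_bandwidth=False`` reverts to per-class bandwidths.
    """
    train, h = {}, {}
    for cls in (0, 1):
        pts = x[y == cls]
        if pts.shape[0] < MIN_DENSITY_POINTS:
            raise ValueError(
                f"class {cls} has only {pts.shape[0]} points on the density half"
            )
        train[cls] = pts.copy()

    def _h(pts: np.ndarray) -> np.ndarray:
        if bandwidth_rule == "fixed":
            return np.maximum(np.full(pts.shape[1], float(fixed_bandwidth)), 1e-3)
        # per-dimension rule with d=2, matching the bivariate product kernel
        return np.stack(
            [bandwidths(pts[:, [c, c]], bandwidth_rule)[0] for c in range(pts.shape[1])]
        )

    if pooled_bandwidth:
        shared = _h(x)
        h = {0: shared, 1: shared.copy()}
    else:
        h = {cls: _h(train[cls]) for cls in (0, 1)}
    return PairDensityModel(component_ids=list(component_ids), train=train, h=h)


def _pair_log_densities(
    queries: np.ndarray,
    train: np.ndarray,
    h: np.ndarray,
    pairs: list[tuple[int, int]],
    self_map: np.ndarray | None = None,
) -> np.ndarray:
    """Log pair densities (floored) for every query and pair.

    ``self_map[q]`` gives the training row that *is* query q (or -1); those
    kernel self-terms are excluded (leave-one-out) and the normalisation
    drops to n-1.
    """
    nq, nt = queries.shape[0], train.shape[0]
    p = train.shape[1]
    # per-component kernel matrices, shared across all pairs touching c
    k = np.empty((p, nq, nt))
    for c in range(p):
        k[c] = np.exp(-0.5 * ((queries[:, c, None] - train[None, :, c]) / h[c]) ** 2)
    dens = np.empty((nq, len(pairs)))
    loo = self_map is not None
    if loo:
        has_self = self_map >= 0
        rows = np.flatnonzero(has_self)
        cols = self_map[rows]
    for idx, (i, j) in enumerate(pairs):
        prod = k[i] * k[j]
        sums = prod.sum(axis=1)
        norm = np.full(nq, float(nt))
        if loo and len(rows):
            sums[rows] -= prod[rows, cols]
            norm[rows] = nt - 1
        dens[:, idx] = sums / (norm * h[i] * h[j] * 2.0 * np.pi)
    return np.log(np.maximum(dens, DENSITY_FLOOR))


def density_ratio_features(
    x: np.ndarray | CRDMatrix,
    model: PairDensityModel,
    self_maps: dict[int, np.ndarray] | None = None,
) -> np.ndarray:
    """ln f1/f0 per pair, columns in lexicographic pair order.

    ``self_maps`` (class -> query-row-to-training-row map, -1 when absent)
    enables leave-one-out evaluation for queries that are KDE training points.
    """
    if isinstance(x, CRDMatrix):
        if x.component_ids != model.component_ids:
            raise ValueError("component mismatch between data and density model")
        x = x.to_numpy()
    x = np.asarray(x, dtype=float)
    if x.shape[1] != len(model.component_ids):
        raise ValueError("component mismatch between data and density model")
    pairs = pair_list(x.shape[1])
    logf = {}
    for cls in (0, 1):
        sm = self_maps.get(cls) if self_maps else None
        logf[cls] = _pair_log_densities(x, model.train[cls], model.h[cls], pairs, sm)
    return logf[1] - logf[0]


@dataclass
class FitRecord:
    """One fitted half-split model: densities from one half, logistic from the other."""

    model: PairDensityModel
    logistic: L1LogisticFit
    density_half: np.ndarray    # participant indices used for the KDEs
    logistic_half: np.ndarray


@dataclass
class JdinacFit:
    """Complete multiple-splitting JDINAC fit."""

    component_ids: list
    participant_ids: list
    pairs: list[tuple[int, int]]
    n_repetitions: int
    fits: list[FitRecord]
    differential_weight: np.ndarray       # per pair: #models with nonzero beta
    mean_nonzero_beta: np.ndarray         # per pair: mean of nonzero coefficients
    averaged_probabilities: np.ndarray    # per participant, out-of-sample average
    seed: int
    bandwidth_rule: str = "scott"
    marginal_transform: "NormalScoresTransform | None" = None
    log1: bool = True

    @property
    def max_weight(self) -> int:
        return 2 * self.n_repetitions

    @property
    def inclusion_fraction(self) -> np.ndarray:
        return self.differential_weight / self.max_weight

    def pair_names(self) -> list[tuple[str, str]]:
        return [(self.component_ids[i], self.component_ids[j]) for i, j in self.pairs]


def _stratified_half_split(y: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    half_a: list[int] = []
    half_b: list[int] = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        mid = len(idx) // 2
        if len(idx) % 2 == 1 and rng.random() < 0.5:
            mid += 1
        half_a.extend(idx[:mid])
        half_b.extend(idx[mid:])
    return np.sort(np.array(half_a)), np.sort(np.array(half_b))


def jdinac_fit(
    m: CRDMatrix,
    y: np.ndarray | pd.Series,
    n_repetitions: int = 25,
    seed: int = 0,
    bandwidth_rule: str = "scott",
    fixed_bandwidth: float | None = None,
    pooled_bandwidth: bool = True,
    log1: bool = True,
    marginal_transform: str = "normal_scores",
    inner_folds: int = 5,
    n_lambdas: int = 20,
    one_se: bool = True,
    max_split_retries: int = 20,
) -> JdinacFit:
    """Fit JDINAC by repeated stratified half-splitting.

    Each repetition draws a fresh stratified half-split and fits two models
    (densities on A / logistic on B, then swapped), giving ``2 * T`` fitted
    models in total.  Input ISU values are log(x+1)-transformed unless
    ``log1=False`` (data already transformed or raw-scale analysis wanted).

    ``marginal_transform="normal_scores"`` (the default) additionally maps
    each component through its rank-based normal scores before density
    estimation; the log density ratio is invariant to this in population,
    and the fixed-bandwidth KDE behaves far better without marginal skew.
    ``marginal_transform="none"`` estimates densities on the (log) ISU scale.
    """
    if isinstance(y, pd.Series):
        y = y.to_numpy()
    y = np.asarray(y, dtype=int)
    x = m.to_numpy()
    if log1:
        x = np.log1p(x)
    if marginal_transform == "normal_scores":
        transform = NormalScoresTransform.fit(x)
        x = transform.apply(x)
    elif marginal_transform == "none":
        transform = None
    else:
        raise ValueError(f"unknown marginal_transform {marginal_transform!r}")
    n, p = x.shape
    if len(y) != n:
        raise ValueError("outcome length does not match the matrix")
    if p < 2:
        raise ValueError("need at least 2 components")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    pairs = pair_list(p)
    rng = np.random.default_rng(seed)

    prob_sum = np.zeros(n)
    prob_count = np.zeros(n)
    weight = np.zeros(len(pairs), dtype=int)
    beta_sum = np.zeros(len(pairs))
    fits: list[FitRecord] = []

    for rep in range(n_repetitions):
        for attempt in range(max_split_retries):
            half_a, half_b = _stratified_half_split(y, rng)
            ok = all(
                (y[h] == cls).sum() >= MIN_DENSITY_POINTS
                for h in (half_a, half_b)
                for cls in (0, 1)
            )
            if ok:
                break
        else:
            raise ValueError(
                f"could not draw a half-split with >= {MIN_DENSITY_POINTS} "
                "participants per class"
            )
        for dens_idx, logit_idx in ((half_a, half_b), (half_b, half_a)):
            model = fit_pair_density_model(
                x[dens_idx], y[dens_idx], m.component_ids,
                bandwidth_rule, fixed_bandwidth, pooled_bandwidth,
            )
            feats_fit = density_ratio_features(x[logit_idx], model)
            lfit = fit_l1_logistic_cv(
                feats_fit, y[logit_idx],
                seed=int(rng.integers(2**31)),
                n_folds=inner_folds, n_lambdas=n_lambdas, one_se=one_se,
            )
            nz = lfit.coef != 0
            weight += nz
            beta_sum += np.where(nz, lfit.coef, 0.0)

            # out-of-sample predictions for the density half (leave-one-out
            # kernel sums so a participant's own mass does not leak its label)
            self_maps = {}
            for cls in (0, 1):
                cls_train = dens_idx[y[dens_idx] == cls]
                lookup = {part: t for t, part in enumerate(cls_train)}
                self_maps[cls] = np.array(
                    [lookup.get(part, -1) for part in dens_idx], dtype=int
                )
            feats_oos = density_ratio_features(x[dens_idx], model, self_maps)
            prob = lfit.predict_proba(feats_oos)
            prob_sum[dens_idx] += prob
            prob_count[dens_idx] += 1
            fits.append(FitRecord(model, lfit, dens_idx, logit_idx))

    with np.errstate(invalid="ignore"):
        averaged = np.where(prob_count > 0, prob_sum / np.maximum(prob_count, 1), np.nan)
    mean_nz = np.where(weight > 0, beta_sum / np.maximum(weight, 1), 0.0)
    return JdinacFit(
        component_ids=m.component_ids,
        participant_ids=m.participant_ids,
        pairs=pairs,
        n_repetitions=n_repetitions,
        fits=fits,
        differential_weight=weight,
        mean_nonzero_beta=mean_nz,
        averaged_probabilities=averaged,
        seed=seed,
        bandwidth_rule=bandwidth_rule,
        marginal_transform=transform,
        log1=log1,
    )


@dataclass
class DifferentialNetwork:
    """Component pairs with differential class-conditional dependency."""

    edges: pd.DataFrame   # comp_a, comp_b, weight, fraction, direction
    min_fraction: float
    max_weight: int

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for _, row in self.edges.iterrows():
            g.add_edge(
                row.comp_a, row.comp_b,
                weight=int(row.weight),
                fraction=float(row.fraction),
                direction=row.direction,
            )
        return g


def extract_network(fit: JdinacFit, min_fraction: float = 0.25) -> DifferentialNetwork:
    """Pairs selected in at least ``min_fraction`` of the fitted models.

    Direction is the sign of the mean nonzero coefficient: positive means the
    pair's class-1 dependency raises the predicted risk ("risk"), negative
    means it lowers it ("protective").
    """
    frac = fit.inclusion_fraction
    keep = np.flatnonzero(frac >= min_fraction)
    names = fit.pair_names()
    rows = [
        {
            "comp_a": names[k][0],
            "comp_b": names[k][1],
            "weight": int(fit.differential_weight[k]),
            "fraction": float(frac[k]),
            "direction": "risk" if fit.mean_nonzero_beta[k] > 0 else "protective",
        }
        for k in keep
    ]
    edges = pd.DataFrame(rows, columns=["comp_a", "comp_b", "weight", "fraction", "direction"])
    edges = edges.sort_values(["weight", "comp_a", "comp_b"], ascending=[False, True, True]).reset_index(drop=True)
    return DifferentialNetwork(edges=edges, min_fraction=min_fraction, max_weight=fit.max_weight)


def predict(fit: JdinacFit, m: CRDMatrix) -> np.ndarray:
    """Average predicted asthma probability over all fitted models.

    New data goes through the same preprocessing the fit recorded (log
    transform and, when used, the frozen normal-scores map).
    """
    if m.component_ids != fit.component_ids:
        raise ValueError("component mismatch between new data and the fit")
    x = m.to_numpy()
    if fit.log1:
        x = np.log1p(x)
    if fit.marginal_transform is not None:
        x = fit.marginal_transform.apply(x)
    probs = np.zeros(x.shape[0])
    for rec in fit.fits:
        feats = density_ratio_features(x, rec.model)
        probs += rec.logistic.predict_proba(feats)
    return probs / len(fit.fits)
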
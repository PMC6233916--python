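"""Sensitisation clusters: grouping participants on binary IgE profiles.

Participants are clustered on the Jaccard distance between their dichotomised
sensitisation profiles using Ward-type agglomeration (Lance-Williams Ward.D2
update on the precomputed distances).  The number of clusters is selected by
the Calinski-Harabasz criterion evaluated on the 0/1 profile coordinates, and
cluster membership is related to clinical outcomes via chi-square tests, odds
ratios with Wald intervals, and Kruskal-Wallis tests for continuous measures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import calinski_harabasz_score

from .cohort_io import BinaryProfile, OutcomeTable

logger = logging.getLogger(__name__)


def jaccard_distance(a, b) -> float:
    """``1 - |a AND b| / |a OR b|`` for two binary vectors.

    Undefined (raises) when both vectors are all-zero; the activity filter
    guarantees every retained participant has at least one positive response.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    union = (a | b).sum()
    if union == 0:
        raise ValueError("Jaccard distance undefined for two all-zero profiles")
    return 1.0 - (a & b).sum() / union


def jaccard_distance_matrix(b: BinaryProfile) -> np.ndarray:
    """Square matrix of pairwise Jaccard distances between participants."""
    x = b.to_numpy().astype(bool)
    if (x.sum(axis=1) == 0).any():
        empty = [b.participant_ids[i] for i in np.flatnonzero(x.sum(axis=1) == 0)]
        raise ValueError(f"all-zero profiles violate the filtering contract: {empty[:5]}")
    return squareform(pdist(x, metric="jaccard"))


@dataclass
class SubjectClustering:
    """Ward-on-Jaccard participant clustering with its selection trace."""

    participant_ids: list
    linkage_matrix: np.ndarray
    labels: np.ndarray
    k: int
    criterion_trace: dict[int, float] = field(default_factory=dict)

    def labels_for(self, k: int) -> np.ndarray:
        return fcluster(self.linkage_matrix, t=k, criterion="maxclust")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"participant_id": self.participant_ids, "cluster_id": self.labels}
        )


def ward_cluster(
    b: BinaryProfile,
    k: int | None = None,
    k_range: tuple[int, int] = (2, 8),
) -> SubjectClustering:
    """Cluster participants and (optionally) select k by Calinski-Harabasz.

    Ward linkage is applied to the Jaccard distance matrix through the
    Lance-Williams recurrence (SciPy's ``ward`` on a condensed precomputed
    distance, i.e. the Ward.D2 convention).  When ``k`` is None the number of
    clusters maximising the CH index over ``k_range`` is chosen; the whole
    trace is kept for inspection.
    """
    dist = jaccard_distance_matrix(b)
    n = dist.shape[0]
    lo, hi = k_range
    if k is not None and not 2 <= k <= n:
        raise ValueError(f"k={k} out of range [2, {n}]")
    if k is None and not 2 <= lo <= hi <= n:
        raise ValueError(f"k_range {k_range} out of range [2, {n}]")
    z = linkage(squareform(dist, checks=False), method="ward")
    if (np.diff(z[:, 2]) < -1e-10).any():
        raise AssertionError("Ward linkage produced a height inversion")

    x = b.to_numpy().astype(float)
    trace: dict[int, float] = {}
    if k is None:
        if np.all(x == x[0]):
            raise ValueError("all profiles identical; cluster number undefined")
        for kk in range(lo, hi + 1):
            lab = fcluster(z, t=kk, criterion="maxclust")
            if len(np.unique(lab)) < 2:
                continue
            trace[kk] = float(calinski_harabasz_score(x, lab))
        if not trace:
            raise ValueError("no candidate k produced a valid partition")
        k = max(trace, key=trace.get)
    labels = fcluster(z, t=k, criterion="maxclust")
    return SubjectClustering(
        participant_ids=b.participant_ids,
        linkage_matrix=z,
        labels=labels,
        k=int(k),
        criterion_trace=trace,
    )


def select_k_calinski_harabasz(clustering: SubjectClustering) -> int:
    """Argmax of the CH trace recorded during :func:`ward_cluster`."""
    if not clustering.criterion_trace:
        raise ValueError("clustering carries no criterion trace (k was fixed)")
    return max(clustering.criterion_trace, key=clustering.criterion_trace.get)


# ---------------------------------------------------------------------------
# Cluster-outcome associations
# ---------------------------------------------------------------------------

@dataclass
class OddsRatioResult:
    cluster: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    table: np.ndarray
    continuity_corrected: bool


@dataclass
class AssociationReport:
    """Association statistics between cluster membership and outcomes."""

    chi2: dict[str, dict]
    odds_ratios: dict[str, list[OddsRatioResult]]
    kruskal_wallis: dict[str, dict]

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "odds_ratios": {
                outcome: [
                    {
                        "cluster": r.cluster,
                        "odds_ratio": r.odds_ratio,
                        "ci_low": r.ci_low,
                        "ci_high": r.ci_high,
                        "p_value": r.p_value,
                        "continuity_corrected": r.continuity_corrected,
                    }
                    for r in rows
                ]
                for outcome, rows in self.odds_ratios.items()
            },
            "kruskal_wallis": self.kruskal_wallis,
        }


def odds_ratio_wald(a: float, b: float, c: float, d: float) -> tuple[float, float, float, float, bool]:
    """OR = ad/bc with Wald 95% CI on the log scale and a two-sided z p-value.

    A zero cell triggers the Haldane-Anscombe 0.5 correction (flagged).
    """
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = np.log(or_) / se
    p = 2 * stats.norm.sf(abs(z))
    ci_low = float(np.exp(np.log(or_) - 1.96 * se))
    ci_high = float(np.exp(np.log(or_) + 1.96 * se))
    return float(or_), ci_low, ci_high, float(p), corrected


def _chi2_kx2(table: np.ndarray, rng: np.random.Generator | None = None) -> dict:
    """Pearson chi-square on a k x 2 table, no continuity correction.

    When any expected count is below 5 a Monte-Carlo p-value (conditional on
    the margins) replaces the asymptotic one.
    """
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    mode = "asymptotic"
    if (expected < 5).any():
        rng = rng or np.random.default_rng(0)
        n_sim = 2000
        row_sums = table.sum(axis=1)
        col_p = table.sum(axis=0) / table.sum()
        count = 0
        for _ in range(n_sim):
            sim = np.stack([rng.multinomial(r, col_p) for r in row_sums])
            sim_exp = np.outer(sim.sum(1), sim.sum(0)) / sim.sum()
            with np.errstate(divide="ignore", invalid="ignore"):
                s = np.nansum((sim - sim_exp) ** 2 / sim_exp)
            count += s >= chi2 - 1e-12
        p = (count + 1) / (n_sim + 1)
        mode = "monte_carlo"
    return {"statistic": float(chi2), "p_value": float(p), "dof": int(dof), "mode": mode}


def associate_outcomes(
    clustering: SubjectClustering,
    outcomes: OutcomeTable,
    reference: str = "rest",
    seed: int = 0,
) -> AssociationReport:
    """Cluster-outcome association statistics.

    Per binary outcome: a k x 2 chi-square test and per-cluster odds ratios.
    The OR reference group defaults to all *other* retained participants
    (``reference="rest"``); ``reference=<cluster id>`` uses that cluster as
    the comparison group instead.  Continuous outcomes get a Kruskal-Wallis
    test across clusters.
    """
    outcomes = outcomes.aligned_to(clustering.participant_ids)
    labels = clustering.labels
    cluster_ids = np.unique(labels)
    rng = np.random.default_rng(seed)

    chi2_results: dict[str, dict] = {}
    or_results: dict[str, list[OddsRatioResult]] = {}
    for outcome in outcomes.binary.columns:
        y = outcomes.binary[outcome].to_numpy()
        table = np.stack(
            [[(y[labels == c] == 1).sum(), (y[labels == c] == 0).sum()] for c in cluster_ids]
        )
        chi2_results[outcome] = _chi2_kx2(table, rng)
        rows = []
        for c in cluster_ids:
            in_c = labels == c
            if reference == "rest":
                ref = ~in_c
            else:
                ref = labels == int(reference)
                if c == int(reference):
                    continue
            a = int((y[in_c] == 1).sum())
            b = int((y[in_c] == 0).sum())
            cc = int((y[ref] == 1).sum())
            dd = int((y[ref] == 0).sum())
            or_, lo, hi, p, corr = odds_ratio_wald(a, b, cc, dd)
            rows.append(
                OddsRatioResult(
                    cluster=int(c),
                    odds_ratio=or_,
                    ci_low=lo,
                    ci_high=hi,
                    p_value=p,
                    table=np.array([[a, b], [cc, dd]]),
                    continuity_corrected=corr,
                )
            )
        or_results[outcome] = rows

    kw_results: dict[str, dict] = {}
    for col in outcomes.continuous.columns:
        v = outcomes.continuous[col].to_numpy(dtype=float)
        groups = [v[labels == c] for c in cluster_ids]
        groups = [g[~np.isnan(g)] for g in groups]
        if any(len(g) == 0 for g in groups):
            logger.warning("Kruskal-Wallis skipped for %s: empty group", col)
            continue
        h, p = stats.kruskal(*groups)
        kw_results[col] = {"statistic": float(h), "p_value": float(p)}

    return AssociationReport(chi2=chi2_results, odds_ratios=or_results, kruskal_wallis=kw_results)
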
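"""Bipartite views linking participant groups to allergen components.

Participants are aggregated into groups by (sensitisation cluster, asthma
status); each group is connected to every component at least one of its
members is positive to, with the count of positive members as edge weight.
A companion table quantifies how asthma odds change with the number of
positive responses to a chosen component subset.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .cohort_io import BinaryProfile, OutcomeTable
from .components import ComponentClustering
from .subjects import SubjectClustering, odds_ratio_wald


def build_bipartite(
    b: BinaryProfile,
    subject_clusters: SubjectClustering,
    component_clusters: ComponentClustering | None,
    outcomes: OutcomeTable,
) -> nx.Graph:
    """Group-by-component bipartite graph.

    Group nodes are ``grp|c<cluster>|a<status>`` with size attributes;
    component nodes carry their component-cluster id.  Edge weight (g, c) is
    the number of group members positive to component c; zero-weight edges
    are omitted.  Total edge weight equals the number of positive entries in
    the profile (conservation).
    """
    if subject_clusters.participant_ids != b.participant_ids:
        raise ValueError("subject clustering does not cover the binary profile")
    outcomes = outcomes.aligned_to(b.participant_ids)
    asthma = outcomes.binary["asthma"].to_numpy()
    labels = subject_clusters.labels
    x = b.to_numpy()

    comp_cluster = {}
    if component_clusters is not None:
        comp_cluster = dict(zip(component_clusters.component_ids, component_clusters.labels))

    g = nx.Graph()
    for cid in b.component_ids:
        g.add_node(cid, bipartite="component", component_cluster=int(comp_cluster.get(cid, 0)))
    for cluster in np.unique(labels):
        for status in (0, 1):
            members = (labels == cluster) & (asthma == status)
            if not members.any():
                continue
            gname = f"grp|c{cluster}|a{status}"
            g.add_node(
                gname,
                bipartite="group",
                cluster=int(cluster),
                asthma_status=int(status),
                size=int(members.sum()),
            )
            counts = x[members].sum(axis=0)
            for j, cid in enumerate(b.component_ids):
                if counts[j] > 0:
                    g.add_edge(gname, cid, weight=int(counts[j]))
    return g


def multi_positivity_risk(
    b: BinaryProfile,
    outcomes: OutcomeTable,
    component_subset: list,
) -> pd.DataFrame:
    """Asthma odds by number of positive responses within ``component_subset``.

    Strata are exact positivity counts; counts of 0 or 1 form the reference
    stratum, and every stratum with >= 2 positives gets an odds ratio against
    it (Wald 95% CI).  Empty or odds-degenerate strata are flagged with NaN.
    """
    if not component_subset:
        raise ValueError("component subset is empty")
    missing = [c for c in component_subset if c not in b.data.columns]
    if missing:
        raise ValueError(f"components not in profile: {missing[:5]}")
    outcomes = outcomes.aligned_to(b.participant_ids)
    asthma = outcomes.binary["asthma"].to_numpy()
    counts = b.data[component_subset].to_numpy().sum(axis=1)

    ref = counts <= 1
    ref_cases = int(asthma[ref].sum())
    ref_ctrl = int((~asthma.astype(bool))[ref].sum())
    rows = [
        {
            "n_positive": "0-1 (reference)",
            "n": int(ref.sum()),
            "cases": ref_cases,
            "odds_ratio": 1.0 if ref.sum() else np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
        }
    ]
    for c in range(2, counts.max() + 1):
        stratum = counts == c
        n = int(stratum.sum())
        cases = int(asthma[stratum].sum())
        if n == 0 or ref.sum() == 0:
            rows.append({"n_positive": c, "n": n, "cases": cases,
                         "odds_ratio": np.nan, "ci_low": np.nan, "ci_high": np.nan})
            continue
        or_, lo, hi, _, _ = odds_ratio_wald(cases, n - cases, ref_cases, ref_ctrl)
        rows.append({"n_positive": c, "n": n, "cases": cases,
                     "odds_ratio": or_, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)
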
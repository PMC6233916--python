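"""End-to-end analysis pipeline and its configuration.

Stage order: ingest -> dichotomise/filter -> component clustering ->
sensitisation clustering -> bipartite views -> penalised-LR baseline vs
pairwise density-ratio classifier -> differential network -> reports.  A
validation mode re-runs the frozen pipeline from scratch on a second dataset
(its own active set, as in a narrow external validation) and compares the
resulting differential networks by edge overlap.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import bipartite as _bipartite
from . import cohort_io, components, evaluate, jdinac, subjects

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All pipeline knobs in one place; defaults mirror the analysis protocol."""

    crd_path: str = ""
    outcomes_path: str = ""
    seed: int = 0
    positivity_threshold: float = 0.30
    min_prevalence: float = 0.05
    cut_height: float = 0.40
    network_min_fraction: float = 0.25
    edge_min_dcor: float = 0.3
    cv_folds: int = 10
    cv_repetitions: int = 50
    jdinac_repetitions: int = 25
    bandwidth_rule: str = "scott"
    dcor_on_log1: bool = True
    missing_to_zero: bool = False
    subject_k: int | None = None
    subject_k_range: tuple[int, int] = (2, 8)
    or_reference: str = "rest"
    classification_threshold: float = 0.5

    def validate(self) -> None:
        checks = [
            (self.positivity_threshold > 0, "positivity_threshold must be > 0"),
            (0 < self.min_prevalence < 1, "min_prevalence must be in (0,1)"),
            (0 <= self.cut_height <= 1, "cut_height must be in [0,1]"),
            (0 < self.network_min_fraction, "network_min_fraction must be > 0"),
            (self.cv_folds >= 2, "cv_folds must be >= 2"),
            (self.cv_repetitions >= 1, "cv_repetitions must be >= 1"),
            (self.jdinac_repetitions >= 1, "jdinac_repetitions must be >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise PipelineError(f"config: {msg}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Flat ``key = value`` text config; unknown keys are an error."""
        cfg = cls()
        valid = set(asdict(cfg))
        for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise PipelineError(f"config line {line_no}: expected key = value")
            key, raw = (s.strip() for s in line.split("=", 1))
            if key not in valid:
                raise PipelineError(f"config line {line_no}: unknown key {key!r}")
            current = getattr(cfg, key)
            if key == "subject_k":
                value = None if raw.lower() in ("none", "") else int(raw)
            elif key == "subject_k_range":
                value = tuple(int(v) for v in raw.split(","))
            elif isinstance(current, bool):
                value = raw.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                value = int(raw)
            elif isinstance(current, float):
                value = float(raw)
            else:
                value = raw
            setattr(cfg, key, value)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["subject_k_range"] = list(self.subject_k_range)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _json_default(obj):
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default))


def run(
    config: PipelineConfig,
    outdir,
    crd: cohort_io.CRDMatrix | None = None,
    outcomes: cohort_io.OutcomeTable | None = None,
    evaluate_models: bool = True,
) -> Path:
    """Run the full analysis; returns the run directory.

    Inputs may be passed in memory (``crd``/``outcomes``) or read from the
    paths in the config.  Every stage's outputs are written under ``outdir``
    along with ``summary.json`` and a checksum manifest.  Deterministic for a
    fixed config and seed (timings excluded).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    summary: dict = {"config": config.to_dict()}
    stage = "ingest"
    try:
        t0 = time.perf_counter()
        if crd is None:
            crd = cohort_io.read_crd(config.crd_path, missing_to_zero=config.missing_to_zero)
        if outcomes is None:
            outcomes = cohort_io.read_outcomes(config.outcomes_path)
        timings[stage] = time.perf_counter() - t0

        stage = "filter"
        t0 = time.perf_counter()
        profile = cohort_io.dichotomise(crd, config.positivity_threshold)
        fb, fm, report = cohort_io.filter_active(profile, crd, config.min_prevalence)
        outcomes_f = outcomes.aligned_to(fb.participant_ids)
        cohort_io.write_crd(fm, outdir / "filtered_crd.csv")
        cohort_io.write_crd(fb, outdir / "filtered_profile.csv")
        _write_json(outdir / "filter_report.json", report.to_dict())
        summary["filter"] = report.to_dict()
        timings[stage] = time.perf_counter() - t0

        stage = "component_clusters"
        t0 = time.perf_counter()
        diss = components.dissimilarity_matrix(fm, log1=config.dcor_on_log1)
        diss.data.to_csv(outdir / "dissimilarity.csv")
        cclust = components.agglomerative_cluster(diss, cut_height=config.cut_height)
        cclust.to_frame().to_csv(outdir / "component_clusters.csv", index=False)
        k = cclust.n_clusters
        comparators = {}
        if 2 <= k <= len(diss.component_ids):
            diana = components.divisive_cluster(diss, k)
            pam = components.pam_cluster(diss, k)
            comparators = {
                "rand_vs_diana": components.rand_index(cclust.labels, diana),
                "rand_vs_pam": components.rand_index(cclust.labels, pam),
            }
        graph = components.build_connectivity_graph(diss, cclust, config.edge_min_dcor)
        import networkx as nx

        nx.write_graphml(graph, outdir / "connectivity.graphml")
        edges = [f"{u}\t{v}\t{d['dcor']:.6f}" for u, v, d in graph.edges(data=True)]
        (outdir / "connectivity_edges.tsv").write_text(
            "source\ttarget\tdcor\n" + "\n".join(edges) + ("\n" if edges else "")
        )
        summary["component_clusters"] = {
            "n_clusters": k,
            "n_singletons": int(cclust.singleton_flags.sum()),
            **{key: round(v, 6) for key, v in comparators.items()},
        }
        timings[stage] = time.perf_counter() - t0

        stage = "sensitisation_clusters"
        t0 = time.perf_counter()
        sclust = subjects.ward_cluster(fb, k=config.subject_k, k_range=config.subject_k_range)
        sclust.to_frame().to_csv(outdir / "sensitisation_clusters.csv", index=False)
        assoc = subjects.associate_outcomes(
            sclust, outcomes_f, reference=config.or_reference, seed=config.seed
        )
        _write_json(outdir / "associations.json", assoc.to_dict())
        summary["sensitisation_clusters"] = {
            "k": sclust.k,
            "criterion_trace": {str(kk): round(v, 4) for kk, v in sclust.criterion_trace.items()},
            "cluster_sizes": {
                str(c): int((sclust.labels == c).sum()) for c in np.unique(sclust.labels)
            },
        }
        timings[stage] = time.perf_counter() - t0

        stage = "bipartite"
        t0 = time.perf_counter()
        bg = _bipartite.build_bipartite(fb, sclust, cclust, outcomes_f)
        nx.write_graphml(bg, outdir / "bipartite.graphml")
        timings[stage] = time.perf_counter() - t0

        stage = "classification"
        t0 = time.perf_counter()
        y = outcomes_f.binary["asthma"].to_numpy()
        jfit = jdinac.jdinac_fit(
            fm, y,
            n_repetitions=config.jdinac_repetitions,
            seed=config.seed,
            bandwidth_rule=config.bandwidth_rule,
        )
        net = jdinac.extract_network(jfit, config.network_min_fraction)
        net.edges.to_csv(outdir / "differential_network.tsv", sep="\t", index=False)
        nx.write_graphml(net.to_graph(), outdir / "differential_network.graphml")
        jdinac_report = evaluate.performance_report(
            y, jfit.averaged_probabilities,
            threshold=config.classification_threshold,
            protocol={"model": "jdinac", "driver": "half-split averaging",
                      "n_repetitions": config.jdinac_repetitions, "seed": config.seed},
        )
        np.savetxt(
            outdir / "jdinac_probabilities.csv",
            np.column_stack([np.arange(len(y)), jfit.averaged_probabilities]),
            delimiter=",", header="row,probability", comments="",
        )
        if evaluate_models:
            lr_report = evaluate.repeated_cv_evaluate(
                {"model": "penalised_lr"}, fm, y,
                folds=config.cv_folds, repetitions=config.cv_repetitions,
                seed=config.seed, threshold=config.classification_threshold,
            )
            _write_json(outdir / "baseline_report.json", lr_report.to_dict())
            summary["baseline"] = lr_report.to_dict()["metrics"]
        _write_json(outdir / "jdinac_report.json", jdinac_report.to_dict())
        _write_json(
            outdir / "fit_metadata.json",
            {
                "n_repetitions": config.jdinac_repetitions,
                "bandwidth_rule": config.bandwidth_rule,
                "seed": config.seed,
                "n_pairs": len(jfit.pairs),
            },
        )
        summary["jdinac"] = jdinac_report.to_dict()["metrics"]
        summary["differential_network"] = {
            "n_edges": int(len(net.edges)),
            "edges": net.edges.to_dict(orient="records"),
        }
        timings[stage] = time.perf_counter() - t0
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage context is the point
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    _write_json(outdir / "summary.json", summary)
    manifest = {
        "files": {
            f.name: _sha256(f)
            for f in sorted(outdir.iterdir())
            if f.is_file() and f.name != "manifest.json"
        },
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
    }
    _write_json(outdir / "manifest.json", manifest)
    return outdir


def verify_manifest(run_dir) -> bool:
    """Re-hash the run directory against its manifest."""
    run_dir = Path(run_dir)
    manifest = json.loads((run_dir / "manifest.json").read_text())
    return all(
        (run_dir / name).is_file() and _sha256(run_dir / name) == digest
        for name, digest in manifest["files"].items()
    )


def validate(
    frozen_run_dir,
    config: PipelineConfig,
    outdir,
    crd: cohort_io.CRDMatrix | None = None,
    outcomes: cohort_io.OutcomeTable | None = None,
) -> dict:
    """Narrow external validation: refit from scratch on a second dataset.

    The new dataset goes through its own filtering (its own active set) and
    model fits; the two differential networks are then compared by Jaccard
    overlap of their edge sets.  Component name sets must intersect.
    """
    frozen_run_dir = Path(frozen_run_dir)
    frozen_summary = json.loads((frozen_run_dir / "summary.json").read_text())
    frozen_edges = {
        tuple(sorted((e["comp_a"], e["comp_b"])))
        for e in frozen_summary["differential_network"]["edges"]
    }
    if crd is None:
        crd = cohort_io.read_crd(config.crd_path, missing_to_zero=config.missing_to_zero)
    frozen_components = set(
        json.loads((frozen_run_dir / "filter_report.json").read_text())["dropped_components"]
    )
    # reconstruct the frozen active set from the filtered matrix header
    frozen_active = set(
        cohort_io.read_crd(frozen_run_dir / "filtered_crd.csv").component_ids
    )
    overlap = frozen_active | frozen_components
    if not overlap & set(crd.component_ids):
        raise PipelineError("validation data shares no components with the frozen run")
    logger.info(
        "validation: %d/%d components shared with the frozen run",
        len(overlap & set(crd.component_ids)), len(crd.component_ids),
    )
    run(config, outdir, crd=crd, outcomes=outcomes)
    new_summary = json.loads((Path(outdir) / "summary.json").read_text())
    new_edges = {
        tuple(sorted((e["comp_a"], e["comp_b"])))
        for e in new_summary["differential_network"]["edges"]
    }
    union = frozen_edges | new_edges
    result = {
        "frozen_edges": sorted(frozen_edges),
        "validation_edges": sorted(new_edges),
        "shared_edges": sorted(frozen_edges & new_edges),
        "edge_jaccard": (len(frozen_edges & new_edges) / len(union)) if union else 1.0,
    }
    _write_json(Path(outdir) / "validation_report.json", result)
    return result
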
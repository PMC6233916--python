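"""Synthetic CRD cohorts with planted structure.

The generator emulates the statistical features the analysis pipeline relies
on, without attempting to be a biological simulator:

* a **Gaussian copula** latent layer with a global "atopy" factor (children
  prone to sensitisation react to many components at once) plus
  block-exchangeable correlation for designated component blocks, mimicking
  protein-family co-sensitisation;
* **zero-inflated log-normal marginals** on the ISU scale: values are
  ``exp(mu + sigma * z) - shift`` truncated at zero, so below-detection
  responses come out as exact zeros (correlated with the latent layer, as in
  real assays), with an optional independent structural-zero mask on top;
* three **outcome regimes**: ``null`` (outcome independent of IgE),
  ``marginal`` (logistic in single-component levels) and
  ``interaction_only`` (class-conditional copula correlations differ for
  designated component pairs while every marginal is identical across
  classes — dependence structure is the only signal).

The ``interaction_only`` regime is exactly the signal a pairwise
density-ratio classifier claims to detect and a main-effects logistic
regression cannot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_io import BinaryProfile, CRDMatrix, OutcomeTable


class ConfigError(ValueError):
    """Raised for infeasible cohort configurations."""


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort draw.

    ``block_spec`` lists ``(size, within_block_latent_corr)`` for consecutive
    component blocks starting at component 0; remaining components are
    singletons.  ``atopy_loading`` is the loading of the shared latent factor
    on every component (squared loading = baseline between-component latent
    correlation).  ``differential_pairs`` entries are
    ``(i, j, corr_in_cases, corr_in_controls)`` on the latent scale and only
    take effect in the ``interaction_only`` regime.
    """

    n_participants: int = 300
    n_components: int = 10
    block_spec: list[tuple[int, float]] = field(default_factory=list)
    atopy_loading: float = 0.0
    zero_inflation: float | np.ndarray = 0.0
    isu_mu: float | np.ndarray = -2.0
    isu_sigma: float | np.ndarray = 1.5
    isu_shift: float | np.ndarray = 0.0
    prone_fraction: float = 1.0
    nonprone_shift: float = 0.0
    outcome_prevalence: float = 0.3
    signal_regime: str = "null"
    marginal_components: list[int] = field(default_factory=list)
    marginal_effect: float = 1.0
    differential_pairs: list[tuple[int, int, float, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        p = self.n_components
        if self.n_participants < 2 or p < 1:
            raise ConfigError("need at least 2 participants and 1 component")
        if sum(s for s, _ in self.block_spec) > p:
            raise ConfigError("block sizes sum to more than n_components")
        for size, rho in self.block_spec:
            if size < 1 or not -1 < rho < 1:
                raise ConfigError(f"invalid block ({size}, {rho})")
        if not 0 < self.outcome_prevalence < 1:
            raise ConfigError("outcome_prevalence must be in (0, 1)")
        if not 0 <= self.atopy_loading < 1:
            raise ConfigError("atopy_loading must be in [0, 1)")
        if self.signal_regime not in ("null", "marginal", "interaction_only"):
            raise ConfigError(f"unknown signal_regime {self.signal_regime!r}")
        for i, j, rc, rn in self.differential_pairs:
            if not (0 <= i < p and 0 <= j < p and i != j):
                raise ConfigError(f"differential pair ({i}, {j}) out of range")
            if not (-1 < rc < 1 and -1 < rn < 1):
                raise ConfigError("differential correlations must be in (-1, 1)")
        zi = np.asarray(self.zero_inflation, dtype=float)
        if (zi < 0).any() or (zi >= 1).any():
            raise ConfigError("zero_inflation must be in [0, 1)")
        if not 0 < self.prone_fraction <= 1:
            raise ConfigError("prone_fraction must be in (0, 1]")
        if self.nonprone_shift < 0:
            raise ConfigError("nonprone_shift must be >= 0")

    def _per_component(self, value) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(value, dtype=float), (self.n_components,))
        return arr.copy()


@dataclass
class PlantedTruth:
    """Ground truth planted into a synthetic cohort."""

    component_blocks: np.ndarray          # block id per component; 0 = singleton
    subject_clusters: np.ndarray | None   # archetype id per participant, if any
    differential_pairs: list[tuple[int, int, float, float]]

    def to_json(self, path) -> None:
        payload = {
            "component_blocks": self.component_blocks.tolist(),
            "subject_clusters": None
            if self.subject_clusters is None
            else np.asarray(self.subject_clusters).tolist(),
            "differential_pairs": [list(p) for p in self.differential_pairs],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            component_blocks=np.asarray(d["component_blocks"]),
            subject_clusters=None
            if d["subject_clusters"] is None
            else np.asarray(d["subject_clusters"]),
            differential_pairs=[tuple(p) for p in d["differential_pairs"]],
        )


def _latent_correlation(cfg: CohortConfig) -> np.ndarray:
    """Baseline latent correlation: atopy factor plus exchangeable blocks."""
    p = cfg.n_components
    lam2 = cfg.atopy_loading**2
    corr = np.full((p, p), lam2)
    start = 0
    for size, rho in cfg.block_spec:
        blk = slice(start, start + size)
        # within-block total correlation: lam2 + (1 - lam2) * rho
        corr[blk, blk] = lam2 + (1.0 - lam2) * rho
        start += size
    np.fill_diagonal(corr, 1.0)
    return corr


def _class_correlations(cfg: CohortConfig, base: np.ndarray) -> dict[int, np.ndarray]:
    """Per-class latent correlation with planted differential pairs applied."""
    mats = {0: base.copy(), 1: base.copy()}
    for i, j, r_case, r_control in cfg.differential_pairs:
        mats[1][i, j] = mats[1][j, i] = r_case
        mats[0][i, j] = mats[0][j, i] = r_control
    for y, mat in mats.items():
        w = np.linalg.eigvalsh(mat)
        if w.min() < -1e-10:
            raise ConfigError(
                f"latent correlation for class {y} is not positive semidefinite "
                f"(min eigenvalue {w.min():.3g}); check block/differential-pair "
                "correlations"
            )
    return mats


def _sample_latent(rng: np.random.Generator, corr: np.ndarray, n: int) -> np.ndarray:
    # eigen decomposition is stabler than Cholesky for near-singular blocks
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    root = v * np.sqrt(w)
    return rng.standard_normal((n, corr.shape[0])) @ root.T


def _isu_from_latent(cfg: CohortConfig, z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    mu = cfg._per_component(cfg.isu_mu)
    sigma = cfg._per_component(cfg.isu_sigma)
    shift = cfg._per_component(cfg.isu_shift)
    x = np.exp(mu + sigma * z) - shift
    np.clip(x, 0.0, None, out=x)
    zi = cfg._per_component(cfg.zero_inflation)
    if (zi > 0).any():
        mask = rng.random(x.shape) < zi
        x[mask] = 0.0
    return x


def _calibrate_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Intercept such that mean logistic probability equals ``prevalence``."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.mean(1.0 / (1.0 + np.exp(-(eta + mid)))) < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _block_labels(cfg: CohortConfig) -> np.ndarray:
    labels = np.zeros(cfg.n_components, dtype=int)
    start = 0
    for b, (size, _) in enumerate(cfg.block_spec, start=1):
        labels[start : start + size] = b
        start += size
    return labels


def generate_cohort(cfg: CohortConfig) -> tuple[CRDMatrix, OutcomeTable, PlantedTruth]:
    """Draw one cohort: ISU matrix, outcomes and the planted ground truth.

    Deterministic for a fixed config (including seed).  In the
    ``interaction_only`` regime outcomes are drawn first and the latent layer
    is sampled class-conditionally so that marginal distributions are
    identical across classes by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_participants, cfg.n_components
    base = _latent_correlation(cfg)

    # sensitisation-prone gate: non-prone children have every latent score
    # shifted down, concentrating positivity without raising between-component
    # correlation among the prone.  Drawn first so the stream layout is the
    # same in every regime; independent of the outcome by construction.
    prone = rng.random(n) < cfg.prone_fraction

    if cfg.signal_regime == "interaction_only":
        mats = _class_correlations(cfg, base)
        y = (rng.random(n) < cfg.outcome_prevalence).astype(np.int8)
        z = np.empty((n, p))
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            z[idx] = _sample_latent(rng, mats[cls], len(idx))
        z[~prone] -= cfg.nonprone_shift
        x = _isu_from_latent(cfg, z, rng)
    else:
        _class_correlations(cfg, base)  # PSD check even without planted pairs
        z = _sample_latent(rng, base, n)
        z[~prone] -= cfg.nonprone_shift
        x = _isu_from_latent(cfg, z, rng)
        if cfg.signal_regime == "null":
            y = (rng.random(n) < cfg.outcome_prevalence).astype(np.int8)
        else:  # marginal
            comps = cfg.marginal_components or [0]
            eta = cfg.marginal_effect * np.log1p(x[:, comps]).sum(axis=1)
            alpha = _calibrate_intercept(eta, cfg.outcome_prevalence)
            prob = 1.0 / (1.0 + np.exp(-(eta + alpha)))
            y = (rng.random(n) < prob).astype(np.int8)

    ids = [f"P{i + 1:04d}" for i in range(n)]
    comps_names = [f"cmp{j + 1:03d}" for j in range(p)]
    crd = CRDMatrix(pd.DataFrame(x, index=ids, columns=comps_names))
    outcomes = OutcomeTable(pd.DataFrame({"asthma": y}, index=ids))
    truth = PlantedTruth(
        component_blocks=_block_labels(cfg),
        subject_clusters=None,
        differential_pairs=list(cfg.differential_pairs),
    )
    return crd, outcomes, truth


# ---------------------------------------------------------------------------
# Reference cohort shape
# ---------------------------------------------------------------------------

#: Sizes of the seven planted component blocks (mite, peanut, lipocalin,
#: grass, PR-10, tree, profilin analogues).
REFERENCE_BLOCK_SIZES = (4, 3, 4, 6, 8, 4, 4)
#: Number of additional "active" singleton components.
REFERENCE_N_ACTIVE_SINGLETONS = 11
#: Total components on the simulated chip.
REFERENCE_N_COMPONENTS = 112
#: Cohort size.
REFERENCE_N_PARTICIPANTS = 461


def reference_cohort_config(
    seed: int = 0,
    signal_regime: str = "marginal",
    differential_pairs: list[tuple[int, int, float, float]] | None = None,
) -> CohortConfig:
    """Config for a birth-cohort-scale CRD dataset.

    112 components: 33 in seven correlated blocks, 11 active singletons and 68
    rare components whose positivity stays below the 5% activity cut-off;
    n = 461 children; roughly 46% sensitised to at least one active component;
    asthma prevalence ≈ 0.34 among the sensitised (0.16 overall), driven by a
    marginal effect on the mite-like block unless another regime is chosen.
    """
    n_active = sum(REFERENCE_BLOCK_SIZES) + REFERENCE_N_ACTIVE_SINGLETONS
    p = REFERENCE_N_COMPONENTS

    # Positivity concentrates in a "sensitisation-prone" subpopulation
    # (roughly half the cohort), mirroring how multi-sensitisation clusters in
    # real cohorts.  Active components get a positivity spread of ~15%-55%
    # among the prone (i.e. ~7%-26% overall), rare components stay below the
    # 5% activity cut-off.
    k = np.arange(n_active)
    target_prev_prone = 0.15 + 0.40 * (k[::-1] / (n_active - 1)) ** 2

    sigma = np.full(p, 1.6)
    shift = np.full(p, 0.08)          # creates correlated exact zeros
    mu = np.empty(p)
    # positivity among the prone: exp(mu + sigma z) - shift > 0.30 <=> z > z*;
    # solve mu from the target prevalence via the normal quantile.
    from scipy.stats import norm

    z_star = norm.isf(target_prev_prone)
    mu[:n_active] = np.log(0.30 + shift[:n_active]) - sigma[:n_active] * z_star
    # Rare components: ~1.5% positivity among the prone.
    z_rare = norm.isf(0.015)
    mu[n_active:] = np.log(0.30 + shift[n_active:]) - sigma[n_active:] * z_rare

    block_spec = [(s, 0.85) for s in REFERENCE_BLOCK_SIZES]
    cfg = CohortConfig(
        n_participants=REFERENCE_N_PARTICIPANTS,
        n_components=p,
        block_spec=block_spec,
        atopy_loading=0.50,
        zero_inflation=0.03,
        isu_mu=mu,
        isu_sigma=sigma,
        isu_shift=shift,
        prone_fraction=0.48,
        nonprone_shift=3.0,
        outcome_prevalence=0.16,
        signal_regime=signal_regime,
        marginal_components=list(range(REFERENCE_BLOCK_SIZES[0])),  # mite-like block
        marginal_effect=1.8,
        differential_pairs=differential_pairs or [],
        seed=seed,
    )
    return cfg


# ---------------------------------------------------------------------------
# Binary archetype profiles for subject-clustering tests
# ---------------------------------------------------------------------------

def archetype_prototypes(n_components: int = 44) -> np.ndarray:
    """Four binary sensitisation archetypes over a 44-component layout.

    1. multiple sensitisation (positives spread over every block plus some
       singletons),
    2. mite-dominated (the first block and mite-like singletons),
    3. grass/tree-dominated (grass and PR-10-like blocks),
    4. lower-grade (a few scattered weak positives).
    """
    bounds = np.cumsum((0,) + REFERENCE_BLOCK_SIZES)
    protos = np.zeros((4, n_components), dtype=np.int8)
    for b in range(len(REFERENCE_BLOCK_SIZES)):                     # multiple
        protos[0, bounds[b] : bounds[b] + 2] = 1
    protos[0, 33:36] = 1
    protos[1, bounds[0] : bounds[1]] = 1                        # mite block
    protos[1, 33:35] = 1
    protos[2, bounds[3] : bounds[5]] = 1                        # grass + PR-10
    protos[3, [bounds[3], bounds[4], bounds[6]]] = 1            # lower-grade
    return protos


def generate_archetype_profiles(
    n_participants: int = 300,
    flip_probability: float = 0.05,
    n_components: int = 44,
    mixing: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
) -> tuple[BinaryProfile, np.ndarray]:
    """Binary profiles from the four archetypes with independent bit-flip noise.

    Returns the profile matrix and the true archetype label per participant.
    All-zero rows (possible after noise) get their archetype's first positive
    bit restored so the filtering contract (every subject has >= 1 positive)
    holds.
    """
    rng = np.random.default_rng(seed)
    protos = archetype_prototypes(n_components)
    labels = rng.choice(len(protos), size=n_participants, p=np.asarray(mixing))
    profiles = protos[labels].copy()
    flips = rng.random(profiles.shape) < flip_probability
    profiles ^= flips.astype(np.int8)
    empty = profiles.sum(axis=1) == 0
    if empty.any():
        first_bit = protos.argmax(axis=1)
        profiles[np.flatnonzero(empty), first_bit[labels[empty]]] = 1
    ids = [f"P{i + 1:04d}" for i in range(n_participants)]
    comps = [f"cmp{j + 1:03d}" for j in range(n_components)]
    b = BinaryProfile(pd.DataFrame(profiles, index=ids, columns=comps))
    return b, labels + 1
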
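"""Seeded synthetic-cohort generator with planted effects.

Builds a log-normal template connectome with a within-hemisphere block
multiplier, multiplies per-subject edge noise on top, plants a strength
deficit at designated nodes in patients, and plants a symptom association
by scaling the triangle edges around a designated node with a latent
per-patient severity that also drives the symptom score.  Ground truth is
returned as a sidecar dict so every inference stage can be validated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from connstat.io import Cohort, ConnectivityMatrix, SubjectRecord
from connstat.metrics import SparsityGrid, threshold_proportional
from connstat.regions import RegionTable, default_region_table, generic_region_table


@dataclass
class SimulationConfig:
    n_nodes: int = 98
    n_mdd: int = 38
    n_hc: int = 40
    # template edge weights ~ LogNormal(mu, sigma); within-hemisphere edges
    # are multiplied by modular_multiplier (> 1 gives hemispheric modules)
    base_weight_mu: float = 3.0
    base_weight_sigma: float = 1.0
    modular_multiplier: float = 2.0
    # multiplicative per-edge subject noise, mean 1, given coefficient of variation
    subject_noise_cv: float = 0.2
    # planted group effect: edges incident to these nodes are scaled by (1-delta)
    # in patients
    strength_deficit_nodes: tuple[int, ...] = ()
    strength_deficit: float = 0.0
    # planted symptom effect: edges among the node's top-m template neighbors
    # are scaled by exp(scale * latent severity) per patient
    clustering_effect_node: int | None = None
    clustering_effect_scale: float = 0.0
    clustering_effect_m: int = 6
    # symptom model (MADRS-like scale per group) and target partial
    # correlation between patient score and the effect node's clustering AUC
    symptom_rho: float = 0.0
    symptom_latent_weight: float | None = None  # set by calibration; default = |symptom_rho|
    madrs_mean_mdd: float = 29.34
    madrs_sd_mdd: float = 5.16
    madrs_mean_hc: float = 0.62
    madrs_sd_hc: float = 1.18
    qids_mean_mdd: float = 14.06
    qids_sd_mdd: float = 4.32
    qids_mean_hc: float = 1.16
    qids_sd_hc: float = 1.79
    # covariate model
    age_mean: float = 37.2
    age_sd: float = 10.9
    male_prob: float = 0.6
    medication_prob: float = 0.7
    volume_mean: float = 500.0
    volume_cv: float = 0.15
    integer_weights: bool = False
    grid: SparsityGrid = field(default_factory=SparsityGrid.default)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.strength_deficit < 1.0):
            raise ValueError("strength_deficit must lie in [0, 1)")
        if not (-1.0 < self.symptom_rho < 1.0):
            raise ValueError("symptom_rho must lie in (-1, 1)")
        for name in ("base_weight_sigma", "modular_multiplier", "volume_mean", "volume_cv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.subject_noise_cv < 0:
            raise ValueError("subject_noise_cv must be nonnegative")
        if self.n_mdd < 1 or self.n_hc < 1:
            raise ValueError("both groups need at least one subject")
        for node in self.strength_deficit_nodes:
            if not (0 <= node < self.n_nodes):
                raise ValueError(f"deficit node {node} out of range")
        if self.clustering_effect_node is not None and not (
            0 <= self.clustering_effect_node < self.n_nodes
        ):
            raise ValueError("clustering_effect_node out of range")

    def region_table(self) -> RegionTable:
        return default_region_table() if self.n_nodes == 98 else generic_region_table(self.n_nodes)


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    s2 = np.log1p(cv**2)
    return rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=size)


def _template_matrix(config: SimulationConfig, region_table: RegionTable, rng) -> np.ndarray:
    N = config.n_nodes
    iu = np.triu_indices(N, k=1)
    w = rng.lognormal(config.base_weight_mu, config.base_weight_sigma, size=len(iu[0]))
    hemi = region_table.table["hemisphere"].to_numpy()
    same = hemi[iu[0]] == hemi[iu[1]]
    w = np.where(same, w * config.modular_multiplier, w)
    T = np.zeros((N, N))
    T[iu] = w
    return T + T.T


def _effect_neighborhood(T: np.ndarray, node: int, m: int) -> np.ndarray:
    """Indices of the node's top-m template neighbors by weight."""
    w = T[node].copy()
    w[node] = -np.inf
    return np.sort(np.argsort(-w, kind="stable")[:m])


def expected_mean_weight(config: SimulationConfig, region_table: RegionTable) -> float:
    """Population mean edge weight implied by the template distribution."""
    hemi = region_table.table["hemisphere"].to_numpy()
    iu = np.triu_indices(config.n_nodes, k=1)
    f_within = float(np.mean(hemi[iu[0]] == hemi[iu[1]]))
    base = np.exp(config.base_weight_mu + config.base_weight_sigma**2 / 2.0)
    return base * (f_within * config.modular_multiplier + (1.0 - f_within))


def _node_clustering_auc(W: np.ndarray, node: int, grid: SparsityGrid, region_table: RegionTable) -> float:
    """Clustering-coefficient AUC of a single node (cheap pilot path)."""
    cm = ConnectivityMatrix(W, region_table)
    vals = np.empty(len(grid))
    for j, S in enumerate(grid.values):
        A = threshold_proportional(cm, S).weights
        mx = A.max()
        if mx == 0:
            vals[j] = 0.0
            continue
        Ahat = np.cbrt(A / mx)
        k = float((A[node] > 0).sum())
        vals[j] = 0.0 if k < 2 else float(Ahat[node] @ Ahat @ Ahat[:, node]) / (k * (k - 1))
    return float(np.trapezoid(vals, grid.values))


def _subject_matrix(
    config: SimulationConfig,
    T: np.ndarray,
    rng: np.random.Generator,
    is_patient: bool,
    severity: float,
    effect_nbrs: np.ndarray | None,
) -> np.ndarray:
    N = config.n_nodes
    iu = np.triu_indices(N, k=1)
    noise = _lognormal_unit_mean(rng, config.subject_noise_cv, len(iu[0]))
    W = np.zeros((N, N))
    W[iu] = T[iu] * noise
    W = W + W.T
    if is_patient:
        if config.strength_deficit > 0:
            for node in config.strength_deficit_nodes:
                W[node, :] *= 1.0 - config.strength_deficit
                W[:, node] *= 1.0 - config.strength_deficit
                W[node, node] = 0.0
        if effect_nbrs is not None and config.clustering_effect_scale > 0:
            mult = np.exp(config.clustering_effect_scale * severity)
            sub = np.ix_(effect_nbrs, effect_nbrs)
            W[sub] = W[sub] * mult
    np.fill_diagonal(W, 0.0)
    if config.integer_weights:
        W = np.round(W)
    return W


def generate_cohort(config: SimulationConfig) -> tuple[Cohort, dict]:
    """Simulate a full cohort; returns (cohort, ground-truth sidecar).

    Fully reproducible from ``config.seed``: the same config yields
    bit-identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    region_table = config.region_table()
    T = _template_matrix(config, region_table, rng)
    effect_nbrs = None
    if config.clustering_effect_node is not None:
        effect_nbrs = _effect_neighborhood(T, config.clustering_effect_node, config.clustering_effect_m)

    n_total = config.n_mdd + config.n_hc
    groups = ["MDD"] * config.n_mdd + ["HC"] * config.n_hc
    severities = rng.standard_normal(n_total)  # only used for patients
    lam = config.symptom_latent_weight
    if lam is None:
        lam = abs(config.symptom_rho)
    sign = -1.0 if config.symptom_rho < 0 else 1.0
    noise_w = np.sqrt(max(0.0, 1.0 - lam**2))

    subjects, matrices = [], []
    for i in range(n_total):
        is_patient = groups[i] == "MDD"
        W = _subject_matrix(config, T, rng, is_patient, severities[i], effect_nbrs)
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 18.0, 80.0))
        sex = "male" if rng.random() < config.male_prob else "female"
        medication = int(rng.random() < config.medication_prob) if is_patient else 0
        volumes = np.clip(
            rng.normal(config.volume_mean, config.volume_mean * config.volume_cv, size=config.n_nodes),
            1.0,
            None,
        )
        eps_m, eps_q = rng.standard_normal(2)
        if is_patient:
            z = sign * lam * severities[i] + noise_w * eps_m
            madrs = config.madrs_mean_mdd + config.madrs_sd_mdd * z
            zq = sign * lam * severities[i] + noise_w * eps_q
            qids = config.qids_mean_mdd + config.qids_sd_mdd * zq
            duration = float(np.clip(rng.lognormal(3.3, 1.0), 0.5, None))
        else:
            madrs = config.madrs_mean_hc + config.madrs_sd_hc * eps_m
            qids = config.qids_mean_hc + config.qids_sd_hc * eps_q
            duration = None
        subjects.append(
            SubjectRecord(
                subject_id=f"sub-{i:03d}",
                group=groups[i],
                age=age,
                sex=sex,
                medication_history=medication,
                madrs=max(0.0, float(madrs)),
                qids=max(0.0, float(qids)),
                episode_duration=duration,
                region_volumes=volumes,
            )
        )
        matrices.append(ConnectivityMatrix(W, region_table))

    truth = {
        "seed": config.seed,
        "strength_deficit_nodes": list(config.strength_deficit_nodes),
        "strength_deficit": config.strength_deficit,
        "clustering_effect_node": config.clustering_effect_node,
        "clustering_effect_neighbors": None if effect_nbrs is None else effect_nbrs.tolist(),
        "symptom_rho": config.symptom_rho,
        "symptom_latent_weight": lam,
        "severities_mdd": severities[: config.n_mdd].tolist(),
    }
    return Cohort(region_table, subjects, matrices), truth


def calibrate_symptom_association(
    config: SimulationConfig,
    n_pilot: int = 2000,
    tol: float = 0.02,
) -> SimulationConfig:
    """Rescale the symptom noise so the realized severity/clustering-AUC
    association matches ``config.symptom_rho``.

    Runs a pilot of ``n_pilot`` patients, measures the realized Spearman
    between the latent severity and the effect node's clustering AUC, and
    bisects on the latent weight so that the simulated score achieves the
    target correlation.  Raises if the target is unattainable given the
    noise floor.
    """
    if config.symptom_rho == 0:
        raise ValueError("calibration requires symptom_rho != 0")
    if config.clustering_effect_node is None or config.clustering_effect_scale <= 0:
        raise ValueError("calibration requires a clustering effect node and positive scale")
    rng = np.random.default_rng([config.seed, 0xCA1])
    region_table = config.region_table()
    T = _template_matrix(config, region_table, rng)
    node = config.clustering_effect_node
    effect_nbrs = _effect_neighborhood(T, node, config.clustering_effect_m)
    z = rng.standard_normal(n_pilot)
    aucs = np.empty(n_pilot)
    for i in range(n_pilot):
        W = _subject_matrix(config, T, rng, True, z[i], effect_nbrs)
        aucs[i] = _node_clustering_auc(W, node, config.grid, region_table)
    eps = rng.standard_normal(n_pilot)
    target = abs(config.symptom_rho)

    def realized(lam: float) -> float:
        score = lam * z + np.sqrt(1.0 - lam**2) * eps
        return float(stats.spearmanr(score, aucs).statistic)

    hi = 0.999
    if realized(hi) < target - tol:
        raise ValueError(
            f"target correlation {config.symptom_rho} unattainable: even a noise-free "
            f"score reaches only {realized(hi):.3f} given the subject noise floor"
        )
    lo = 0.0
    for _ in range(40):
        mid = (lo + hi) / 2.0
        if realized(mid) < target:
            lo = mid
        else:
            hi = mid
    lam = (lo + hi) / 2.0
    return dataclasses.replace(config, symptom_latent_weight=lam)


def write_ground_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
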
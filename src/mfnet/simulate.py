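"""Synthetic study generator with known ground truth.

Emulates the statistical structure the pipeline assumes: a fuzzy-coded
trait table with planted clusters of trait-sharing species, overdispersed
(negative-binomial) community abundances, environmental characteristics,
and ecosystem functions generated as linear combinations of standardized
cluster-abundance and environment predictors plus Gaussian noise.  Every
generator is a pure function of (parameters, seed), so each pipeline
stage can be tested against the planted truth without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .tables import FuzzyTraitTable, SampleMatrix, ValidationError
from .traitnet import ClusterAbundanceTable

DEFAULT_ENV_SPEC: dict[str, tuple] = {
    "mud": ("uniform", 1.0, 40.0),           # % fine particles
    "som": ("uniform", 0.5, 5.0),            # % sediment organic matter
    "shell_hash": ("uniform", 0.0, 30.0),    # % coarse shell fragments
    "water_content": ("uniform", 15.0, 35.0),
}

# One planted cluster effect (partial R^2 0.3) and one planted environment
# effect (partial R^2 0.2) on the first function; the remaining functions
# are pure noise.  Coefficients act on standardized predictors, so a
# coefficient of sqrt(p) with residual sd sqrt(1 - sum p) plants a partial
# R^2 of about p when predictors are near-independent.
DEFAULT_EFFECT_SPEC: tuple[tuple[str, str, float], ...] = (
    ("f1", "c1", math.sqrt(0.3)),
    ("f1", "mud", math.sqrt(0.2)),
)
DEFAULT_FUNCTIONS = ("f1", "f2", "f3", "f4", "f5", "f6", "f7", "f8")


@dataclass
class SimulationParams:
    """Ground-truth parameters of one synthetic study.

    within_overlap
        Probability a species carries each core modality of its own cluster.
    between_noise
        Probability it carries each off-cluster modality.
    n_modalities
        Total modality pool.  The default (180, i.e. disjoint cores of 30
        per cluster) comes from a power analysis of the hypergeometric
        pair test: the within-block excess sharing grows like the core
        size c while its standard deviation grows like sqrt(c), so under
        carriage probabilities 0.8/0.2 a per-pair power above ~95% (and
        hence reliable block recovery) requires cores of roughly 25-30
        modalities.  Real fuzzy-coded tables are far smaller but share
        whole category patterns rather than independent random modalities,
        which this generator deliberately does not emulate.
    abundance_dispersion
        Negative-binomial size parameter k (variance = mu + mu^2/k);
        ``inf`` gives the Poisson limit.
    effect_spec
        (target function, source predictor, coefficient) triples; sources
        name planted clusters (``c1`` ...) or environment variables.
    noise_sd
        Residual sd per function (scalar or mapping); defaults keep total
        signal + noise variance near 1 for the planted function.
    """

    n_clusters: int = 6
    species_per_cluster: int = 6
    n_modalities: int = 180
    n_categories: int = 7
    within_overlap: float = 0.8
    between_noise: float = 0.2
    n_samples: int = 49
    abundance_dispersion: float = 2.0
    mean_abundance: float | Sequence[float] = 20.0
    function_names: tuple[str, ...] = DEFAULT_FUNCTIONS
    effect_spec: tuple[tuple[str, str, float], ...] = DEFAULT_EFFECT_SPEC
    noise_sd: float | Mapping[str, float] = field(
        default_factory=lambda: {"f1": math.sqrt(0.5)})
    env_spec: Mapping[str, tuple] = field(default_factory=lambda: dict(DEFAULT_ENV_SPEC))
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in (("within_overlap", self.within_overlap),
                        ("between_noise", self.between_noise)):
            if not (0 <= p <= 1):
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.n_samples < 4:
            raise ValidationError("n_samples must be >= 4")
        for _, _, coef in self.effect_spec:
            if not np.isfinite(coef):
                raise ValidationError("effect coefficients must be finite")

    def noise_for(self, function: str) -> float:
        if isinstance(self.noise_sd, Mapping):
            return float(self.noise_sd.get(function, 1.0))
        return float(self.noise_sd)

    def mean_for(self, cluster_index: int) -> float:
        if np.isscalar(self.mean_abundance):
            return float(self.mean_abundance)
        return float(self.mean_abundance[cluster_index])


def coefficients_for_partial_r2(partials: Mapping[str, float]) -> tuple[dict[str, float], float]:
    """Coefficients (on standardized predictors) and residual sd planting
    the requested partial R^2 values on near-independent predictors."""
    total = sum(partials.values())
    if total >= 1:
        raise ValidationError("planted partial R^2 values must sum to < 1")
    return {k: math.sqrt(v) for k, v in partials.items()}, math.sqrt(1 - total)


def simulate_traits(p: SimulationParams) -> tuple[FuzzyTraitTable, dict[str, str]]:
    """Fuzzy trait table with planted clusters; returns (table, planted labels).

    Each cluster owns a disjoint core set of ``n_modalities // n_clusters``
    modalities; a member carries each core modality with probability
    ``within_overlap`` and each foreign modality with ``between_noise``.
    Carried modalities get affinities on (0.5, 1], then per-category
    normalization.  A species ending up trait-empty is given one core
    modality so the table stays usable.
    """
    if p.n_clusters * p.species_per_cluster < 2:
        raise ValidationError("need at least 2 species")
    core_size = p.n_modalities // p.n_clusters
    if core_size < 1:
        raise ValidationError(
            f"core sets exceed n_modalities: {p.n_clusters} clusters need at "
            f"least {p.n_clusters} modalities, got {p.n_modalities}")
    rng = np.random.default_rng([p.seed, 1])
    n_species = p.n_clusters * p.species_per_cluster
    modalities = [f"m{j + 1:02d}" for j in range(p.n_modalities)]
    categories = {m: f"cat{j % p.n_categories + 1}" for j, m in enumerate(modalities)}
    species = [f"sp{i + 1:03d}" for i in range(n_species)]
    planted = {s: f"b{i // p.species_per_cluster + 1}" for i, s in enumerate(species)}
    carry = np.zeros((n_species, p.n_modalities), dtype=bool)
    for i in range(n_species):
        block = i // p.species_per_cluster
        core = np.zeros(p.n_modalities, dtype=bool)
        core[block * core_size:(block + 1) * core_size] = True
        u = rng.random(p.n_modalities)
        carry[i] = np.where(core, u < p.within_overlap, u < p.between_noise)
        if not carry[i].any():
            carry[i, block * core_size] = True
    scores = np.where(carry, 0.5 + 0.5 * rng.random(carry.shape), 0.0)
    table = FuzzyTraitTable(species, modalities, categories, scores).normalize()
    return table, planted


def simulate_community(p: SimulationParams) -> tuple[SampleMatrix, SampleMatrix]:
    """Negative-binomial abundances and environmental characteristics."""
    if not (p.abundance_dispersion > 0):
        raise ValidationError("abundance_dispersion must be positive")
    rng = np.random.default_rng([p.seed, 2])
    n_species = p.n_clusters * p.species_per_cluster
    species = [f"sp{i + 1:03d}" for i in range(n_species)]
    counts = np.zeros((p.n_samples, n_species))
    k = p.abundance_dispersion
    for i in range(n_species):
        mu = p.mean_for(i // p.species_per_cluster)
        if mu == 0:
            continue
        if np.isinf(k):
            counts[:, i] = rng.poisson(mu, size=p.n_samples)
        else:
            counts[:, i] = rng.negative_binomial(k, k / (k + mu), size=p.n_samples)
    samples = [f"s{j + 1:02d}" for j in range(p.n_samples)]
    abundance = SampleMatrix(samples, species, counts, kind="abundance")
    env_cols = []
    for var, spec in p.env_spec.items():
        dist, *args = spec
        if dist == "uniform":
            env_cols.append(rng.uniform(args[0], args[1], size=p.n_samples))
        elif dist == "normal":
            env_cols.append(rng.normal(args[0], args[1], size=p.n_samples))
        elif dist == "lognormal":
            env_cols.append(rng.lognormal(args[0], args[1], size=p.n_samples))
        else:
            raise ValidationError(f"unknown environment distribution {dist!r}")
    env = SampleMatrix(samples, list(p.env_spec), np.column_stack(env_cols),
                       kind="environment")
    return abundance, env


def simulate_functions(
    p: SimulationParams,
    clusters: ClusterAbundanceTable | SampleMatrix,
    env: SampleMatrix,
) -> tuple[SampleMatrix, dict]:
    """Function table from planted linear effects; returns (table, truth).

    Each function is the sum of coefficient x standardized source over its
    effects plus Gaussian noise.  The returned ground truth records, per
    function, the realized full R^2 and each source's semi-partial R^2
    computed from the realized design (signal + noise).
    """
    mat = clusters.matrix if isinstance(clusters, ClusterAbundanceTable) else clusters
    rng = np.random.default_rng([p.seed, 3])
    sources: dict[str, np.ndarray] = {}

    def z(var: str) -> np.ndarray:
        if var not in sources:
            if var in mat.variable_ids:
                v = mat.column(var)
            elif var in env.variable_ids:
                v = env.column(var)
            else:
                raise ValidationError(f"unknown effect source {var!r}")
            sd = v.std()
            if sd == 0:
                raise ValidationError(f"effect source {var!r} is constant")
            sources[var] = (v - v.mean()) / sd
        return sources[var]

    n = len(mat.sample_ids)
    values = np.zeros((n, len(p.function_names)))
    truth: dict[str, dict] = {}
    effects_of: dict[str, list[tuple[str, float]]] = {f: [] for f in p.function_names}
    for target, source, coef in p.effect_spec:
        if target not in effects_of:
            raise ValidationError(f"effect targets unknown function {target!r}")
        effects_of[target].append((source, float(coef)))
    for j, fname in enumerate(p.function_names):
        y = np.zeros(n)
        for source, coef in effects_of[fname]:
            y = y + coef * z(source)
        y = y + rng.normal(0.0, p.noise_for(fname), size=n)
        values[:, j] = y
        if effects_of[fname]:
            names = [s for s, _ in effects_of[fname]]
            Z = np.column_stack([z(s) for s in names])
            truth[fname] = {
                "effects": effects_of[fname],
                "r2_full": _ols_r2(y, Z),
                "semi_partial_r2": {
                    s: _ols_r2(y, Z) - (_ols_r2(y, np.delete(Z, k, axis=1))
                                        if Z.shape[1] > 1 else 0.0)
                    for k, s in enumerate(names)
                },
            }
    functions = SampleMatrix(list(mat.sample_ids), list(p.function_names),
                             values, kind="function")
    return functions, truth


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    fitted = Xc @ beta
    tot = float(yc @ yc)
    return float(fitted @ yc) / tot if tot > 0 else 0.0


@dataclass
class SyntheticBundle:
    """Everything one simulated study comprises, plus its ground truth."""

    traits: FuzzyTraitTable
    planted_partition: dict[str, str]
    abundance: SampleMatrix
    environment: SampleMatrix
    cluster_abundance: ClusterAbundanceTable
    functions: SampleMatrix
    truth: dict


def simulate_dataset(p: SimulationParams) -> SyntheticBundle:
    """Generate the full four-table study with planted-cluster aggregation.

    Cluster abundances are aggregated from the *planted* partition (labels
    ``b1`` ... renamed ``c1`` ... in planted order), so downstream effects
    reference the true clusters regardless of what the network stage later
    recovers.
    """
    traits, planted = simulate_traits(p)
    abundance, env = simulate_community(p)
    members: dict[str, list[str]] = {}
    for sp, block in planted.items():
        members.setdefault(block, []).append(sp)
    blocks = sorted(members, key=lambda b: int(b[1:]))
    cols, names, prov = [], [], {}
    for idx, b in enumerate(blocks):
        name = f"c{idx + 1}"
        cols.append(np.column_stack(
            [abundance.column(sp) for sp in members[b]]).sum(axis=1))
        names.append(name)
        prov[name] = members[b]
    clusters = ClusterAbundanceTable(
        matrix=SampleMatrix(list(abundance.sample_ids), names,
                            np.column_stack(cols), kind="abundance"),
        provenance=prov,
    )
    functions, truth = simulate_functions(p, clusters, env)
    return SyntheticBundle(traits, planted, abundance, env, clusters, functions, truth)
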
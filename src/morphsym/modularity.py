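"""Modularity statistics and covariation-model selection.

* The covariance ratio (CR): squared between-module covariances relative
  to the geometric mean of the squared within-module covariances.  CR
  toward 0 means stronger modularity.
* Z_CR effect sizes against a null of random size-preserving landmark
  reassignment, with a resampled distribution of the standardization for
  confidence intervals, and pairwise comparison of modular signal
  (|Z1 - Z2| with an overlap p-value and compact letter grouping).
* A modularity test contrasting the CR of a hypothesized partition
  (bootstrap distribution over specimens) with CRs of arbitrary random
  partitions of the same module sizes.
* Likelihood/AICc selection over covariation models that assign a single
  correlation parameter to groups of landmark pairs (within module m,
  between modules, ...), fitted to the landmark congruence-correlation
  matrix with Fisher-z normal likelihoods.

Both coordinates of a landmark always travel together: the landmark, not
the coordinate column, is the exchangeable unit in every permutation.
"""

from __future__ import annotations

import itertools
import string
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import ModulePartition

__all__ = [
    "ModularSignalResult",
    "SignalComparison",
    "ModularityTestResult",
    "CovariationModel",
    "EmmliResult",
    "covariance_ratio",
    "cr_effect_size",
    "compare_modular_signal",
    "modularity_test",
    "landmark_congruence",
    "emmli_fit",
    "enumerate_covariation_variants",
]


# ---------------------------------------------------------------------------
# covariance ratio


def _cr_from_cov(cov: np.ndarray, lm_labels: np.ndarray) -> float:
    """CR computed from a 2K x 2K covariance matrix and per-landmark labels."""
    col_labels = np.repeat(lm_labels, 2)
    modules = list(dict.fromkeys(lm_labels))
    sq = cov**2
    off = sq.copy()
    np.fill_diagonal(off, 0.0)
    within = {}
    for m in modules:
        mask = col_labels == m
        w = off[np.ix_(mask, mask)].sum()
        if w == 0.0:
            raise ValueError(
                f"module {m!r}: all within-module off-diagonal covariances "
                "are zero; CR undefined"
            )
        within[m] = w
    crs = []
    for a, b in itertools.combinations(modules, 2):
        num = sq[np.ix_(col_labels == a, col_labels == b)].sum()
        crs.append(np.sqrt(num / np.sqrt(within[a] * within[b])))
    return float(np.mean(crs))


def covariance_ratio(shape: np.ndarray, partition: ModulePartition) -> float:
    """Covariance ratio of a shape matrix under a module partition.

    ``shape`` is (n, 2K) with landmark-major column order
    (lm1_x, lm1_y, lm2_x, ...); both coordinates of a landmark inherit its
    module.  For two modules::

        CR = sqrt( sum s_b^2 / sqrt( sum s_w1^2 * sum s_w2^2 ) )

    over squared sample covariances (off-diagonal only within modules);
    for more than two modules, the mean of all pairwise CRs.
    """
    shape = np.asarray(shape, dtype=float)
    if shape.ndim != 2 or shape.shape[0] < 3:
        raise ValueError("shape matrix must be (n >= 3, 2K)")
    if shape.shape[1] != 2 * partition.n_landmarks:
        raise ValueError(
            f"shape has {shape.shape[1]} columns but partition covers "
            f"{partition.n_landmarks} landmarks"
        )
    if partition.module_count < 2:
        raise ValueError("CR needs at least 2 modules")
    cov = np.cov(shape, rowvar=False)
    return _cr_from_cov(cov, partition.labels_array())


# ---------------------------------------------------------------------------
# CR effect size and signal comparison


@dataclass
class ModularSignalResult:
    partition_name: str
    cr: float
    z_cr_mean: float
    z_cr_distribution: np.ndarray
    ci95: tuple[float, float]
    permutations: int
    seed: int


def cr_effect_size(
    shape: np.ndarray,
    partition: ModulePartition,
    permutations: int = 999,
    seed: int = 0,
) -> ModularSignalResult:
    """Standardized modular signal Z_CR with a resampled distribution.

    The null distribution reassigns landmarks to modules at random,
    preserving module sizes; ``Z = (CR_obs - mean_null) / sd_null`` is
    negative when the observed partition is more modular than random.
    The reported distribution repeats the standardization over bootstrap
    resamples of the permutation set, giving the spread that the mean and
    95% CI summarize.
    """
    cr_obs = covariance_ratio(shape, partition)
    cov = np.cov(shape, rowvar=False)
    labels = partition.labels_array()
    rng = np.random.default_rng(seed)
    null = np.empty(permutations)
    for b in range(permutations):
        null[b] = _cr_from_cov(cov, labels[rng.permutation(len(labels))])
    sd = null.std(ddof=1)
    if sd == 0.0:
        raise ValueError("degenerate null: permuted CR values are constant")
    z_dist = np.empty(permutations)
    for b in range(permutations):
        boot = null[rng.integers(0, permutations, permutations)]
        bsd = boot.std(ddof=1)
        z_dist[b] = (cr_obs - boot.mean()) / (bsd if bsd > 0 else sd)
    lo, hi = np.percentile(z_dist, [2.5, 97.5])
    return ModularSignalResult(
        partition_name=partition.name,
        cr=cr_obs,
        z_cr_mean=float(z_dist.mean()),
        z_cr_distribution=z_dist,
        ci95=(float(lo), float(hi)),
        permutations=permutations,
        seed=seed,
    )


@dataclass
class SignalComparison:
    pairwise: pd.DataFrame  # model_1, model_2, delta, p_overlap
    grouping: dict[str, str]  # model name -> letters
    alpha: float


def compare_modular_signal(
    results: list[ModularSignalResult], alpha: float = 0.05
) -> SignalComparison:
    """Pairwise |Z1 - Z2| with overlap p-values and letter grouping.

    ``p_overlap = 2 * min(P(Z_low >= mean Z_high), P(Z_high <= mean Z_low))``
    clipped to [0, 1] — the symmetrized fraction of each distribution lying
    beyond the other's mean.  Models joined by non-significant pairs share
    a letter (compact letter display over maximal cliques of the
    non-significance graph).
    """
    if len(results) < 2:
        raise ValueError("need at least 2 results to compare")
    counts = {r.permutations for r in results}
    if len(counts) > 1:
        raise ValueError("mismatched permutation counts")
    rows = []
    graph = nx.Graph()
    for r in results:
        graph.add_node(r.partition_name)
    for r1, r2 in itertools.combinations(results, 2):
        m1, m2 = r1.z_cr_distribution.mean(), r2.z_cr_distribution.mean()
        lo, hi = (r1, r2) if m1 <= m2 else (r2, r1)
        mlo, mhi = lo.z_cr_distribution.mean(), hi.z_cr_distribution.mean()
        p = 2.0 * min(
            (lo.z_cr_distribution >= mhi).mean(),
            (hi.z_cr_distribution <= mlo).mean(),
        )
        p = float(np.clip(p, 0.0, 1.0))
        rows.append(
            {
                "model_1": r1.partition_name,
                "model_2": r2.partition_name,
                "delta": abs(m1 - m2),
                "p_overlap": p,
            }
        )
        if p >= alpha:
            graph.add_edge(r1.partition_name, r2.partition_name)

    cliques = sorted(
        nx.find_cliques(graph),
        key=lambda c: min(
            i for i, r in enumerate(results) if r.partition_name in c
        ),
    )
    letters: dict[str, list[str]] = {r.partition_name: [] for r in results}
    for letter, clique in zip(string.ascii_lowercase, cliques):
        for name in clique:
            letters[name].append(letter)
    return SignalComparison(
        pairwise=pd.DataFrame(rows),
        grouping={k: "".join(v) for k, v in letters.items()},
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# modularity test against arbitrary partitions


@dataclass
class ModularityTestResult:
    partition_name: str
    cr_observed_mean: float
    cr_observed_distribution: np.ndarray
    cr_arbitrary_distribution: np.ndarray
    p: float
    rounds: int
    seed: int


def modularity_test(
    shape: np.ndarray,
    partition: ModulePartition,
    rounds: int = 10000,
    seed: int = 0,
) -> ModularityTestResult:
    """Test a hypothesized partition's CR against arbitrary partitions.

    The observed distribution shows the sampling spread of the
    hypothesized partition's CR over bootstrap resamples of specimens
    (module membership fixed; shuffling landmarks *within* modules leaves
    CR unchanged, so that jitter is degenerate at the point value).  The
    arbitrary distribution draws random size-preserving reassignments of
    landmarks to modules.  ``p`` is the proportion of arbitrary CR values
    at or below the observed CR (the centre of the degenerate
    within-module-shuffle distribution), with the add-one correction.
    Calibration note: the null of random reassignment treats landmarks as
    exchangeable; on object-symmetric components, where pair members
    mirror each other, partitions keeping pairs intact are favoured a
    priori.
    """
    if rounds < 100:
        warnings.warn("fewer than 100 rounds: the p-value will be unstable", stacklevel=2)
    shape = np.asarray(shape, dtype=float)
    n = shape.shape[0]
    labels = partition.labels_array()
    rng = np.random.default_rng(seed)
    cr_point = covariance_ratio(shape, partition)

    cr_obs = np.empty(rounds)
    for b in range(rounds):
        idx = rng.integers(0, n, n)
        cov = np.cov(shape[idx], rowvar=False)
        cr_obs[b] = _cr_from_cov(cov, labels)

    cov_full = np.cov(shape, rowvar=False)
    cr_arb = np.empty(rounds)
    for b in range(rounds):
        cr_arb[b] = _cr_from_cov(cov_full, labels[rng.permutation(len(labels))])

    p = (float((cr_arb <= cr_point).sum()) + 1.0) / (rounds + 1.0)
    return ModularityTestResult(
        partition_name=partition.name,
        cr_observed_mean=cr_point,
        cr_observed_distribution=cr_obs,
        cr_arbitrary_distribution=cr_arb,
        p=p,
        rounds=rounds,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# likelihood / AICc covariation-model selection


@dataclass(frozen=True)
class CovariationModel:
    """A grouping of landmark pairs into shared-correlation parameters.

    ``within_mode`` is ``"shared"`` (one rho for all within-module pairs)
    or ``"per-module"``; ``between_mode`` is ``"pooled"`` or
    ``"per-pair"`` (one rho per unordered module pair).  A 1-module
    partition yields the flat model: a single rho for every landmark pair.
    """

    name: str
    partition: ModulePartition
    within_mode: str = "shared"
    between_mode: str = "pooled"

    def group_of(self, lm_a: int, lm_b: int) -> str:
        """Parameter-group label for a 1-based unordered landmark pair."""
        ma = self.partition.assignment[lm_a]
        mb = self.partition.assignment[lm_b]
        if self.partition.module_count == 1:
            return "all"
        if ma == mb:
            return f"within:{ma}" if self.within_mode == "per-module" else "within"
        if self.between_mode == "per-pair":
            lo, hi = sorted((ma, mb))
            return f"between:{lo}|{hi}"
        return "between"

    def pair_groups(self) -> dict[tuple[int, int], str]:
        k = self.partition.n_landmarks
        return {
            (a, b): self.group_of(a, b)
            for a, b in itertools.combinations(range(1, k + 1), 2)
        }

    @property
    def k_params(self) -> int:
        return len(set(self.pair_groups().values()))


def enumerate_covariation_variants(
    base_partitions: list[ModulePartition],
) -> list[CovariationModel]:
    """Expand modularity hypotheses into distinct covariation models.

    Each multi-module partition is crossed with {shared, per-module}
    within-correlation and {pooled, per-pair} between-correlation;
    variants inducing the same landmark-pair grouping are deduplicated
    (for a 2-module partition the between crossing collapses, leaving 2
    distinct variants).  A 1-module partition contributes the single flat
    model.
    """
    models: list[CovariationModel] = []
    for part in base_partitions:
        if part.module_count == 1:
            models.append(CovariationModel(name=part.name, partition=part))
            continue
        seen: set[tuple] = set()
        for wmode, bmode in itertools.product(
            ("shared", "per-module"), ("pooled", "per-pair")
        ):
            model = CovariationModel(
                name=f"{part.name}[w:{wmode},b:{bmode}]",
                partition=part,
                within_mode=wmode,
                between_mode=bmode,
            )
            groups = model.pair_groups()
            remap: dict[str, int] = {}
            sig = tuple(
                remap.setdefault(groups[key], len(remap))
                for key in sorted(groups)
            )
            if sig in seen:
                continue
            seen.add(sig)
            models.append(model)
    return models


def landmark_congruence(shape: np.ndarray) -> np.ndarray:
    """Congruence-correlation matrix between landmarks.

    Tucker's congruence coefficient between the centred n x 2 coordinate
    blocks of each landmark pair: the inner product of the flattened
    blocks over the product of their norms.  Lies in [-1, 1].
    """
    shape = np.asarray(shape, dtype=float)
    n, twok = shape.shape
    k = twok // 2
    blocks = shape.reshape(n, k, 2) - shape.reshape(n, k, 2).mean(axis=0)
    flat = blocks.transpose(1, 0, 2).reshape(k, -1)  # (K, 2n)
    norms = np.linalg.norm(flat, axis=1)
    r = (flat @ flat.T) / np.outer(norms, norms)
    np.fill_diagonal(r, 1.0)
    return r


@dataclass
class EmmliResult:
    table: pd.DataFrame  # name, k_params, logL, aicc, delta_aicc, weight
    rho_estimates: dict[str, dict[str, float]] = field(default_factory=dict)
    n_eff: int = 0

    @property
    def best_model(self) -> str:
        return str(self.table.loc[self.table["aicc"].idxmin(), "name"])


def emmli_fit(
    shape: np.ndarray,
    model_registry: list[CovariationModel],
    n_eff: int,
    aicc_sample: str = "n_corr",
) -> EmmliResult:
    """Maximum-likelihood comparison of covariation models.

    Each model's group correlation is the inverse Fisher-z of the mean
    Fisher-z of its member landmark correlations; the log-likelihood sums
    normal log-densities of z(r_ab) with mean z(rho_group) and variance
    1/(n_eff - 3).  AICc penalizes with k = number of rho parameters and
    sample size N = number of landmark correlations (``aicc_sample`` can
    switch to ``"n_eff"``); model weights are exp(-delta/2), normalized.
    """
    if n_eff <= 3:
        raise ValueError("n_eff must exceed 3 for the Fisher-z variance")
    r = landmark_congruence(shape)
    k_lm = r.shape[0]
    pairs = list(itertools.combinations(range(1, k_lm + 1), 2))
    n_corr = len(pairs)
    z = np.arctanh(
        np.clip(np.array([r[a - 1, b - 1] for a, b in pairs]), -0.999999, 0.999999)
    )
    var = 1.0 / (n_eff - 3)

    rows = []
    rho_estimates: dict[str, dict[str, float]] = {}
    for model in model_registry:
        if model.partition.n_landmarks != k_lm:
            raise ValueError(
                f"model {model.name!r} covers {model.partition.n_landmarks} "
                f"landmarks but the data has {k_lm}"
            )
        groups = model.pair_groups()
        labels = np.array([groups[p] for p in pairs])
        uniq = list(dict.fromkeys(labels))
        kp = len(uniq)
        nsize = n_corr if aicc_sample == "n_corr" else n_eff
        if kp >= nsize - 1:
            warnings.warn(
                f"model {model.name!r} skipped: {kp} parameters for "
                f"sample size {nsize}",
                stacklevel=2,
            )
            continue
        logl = 0.0
        rhos: dict[str, float] = {}
        for g in uniq:
            zg = z[labels == g]
            mu = zg.mean()
            rhos[g] = float(np.tanh(mu))
            logl += float(
                -0.5 * len(zg) * np.log(2.0 * np.pi * var)
                - ((zg - mu) ** 2).sum() / (2.0 * var)
            )
        aicc = -2.0 * logl + 2.0 * kp + 2.0 * kp * (kp + 1) / (nsize - kp - 1)
        rows.append(
            {"name": model.name, "k_params": kp, "logL": logl, "aicc": aicc}
        )
        rho_estimates[model.name] = rhos

    if not rows:
        raise ValueError("no fittable model in the registry")
    table = pd.DataFrame(rows)
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    w = np.exp(-table["delta_aicc"] / 2.0)
    table["weight"] = w / w.sum()
    return EmmliResult(table=table, rho_estimates=rho_estimates, n_eff=n_eff)
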
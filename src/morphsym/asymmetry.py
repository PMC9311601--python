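"""Inference on bilateral asymmetry.

Three layers:

* A distance-based two-way Procrustes ANOVA over the ``2 * n * r`` aligned
  copies (original + mirrored per replicate), reporting the sex effect on
  the symmetric component, directional asymmetry (side), their interaction
  (the sex contrast in fluctuating asymmetry) and a pooled error term,
  with p-values by randomization of reduced-model residuals (RRPP) at the
  exchangeable unit appropriate to each term.
* The left-right triangle-area asymmetry descriptor: for every bilateral
  pair the area of the axis-aligned right triangle spanned by the
  anterior axis-reference landmark and the pair member is compared between
  sides, as a percentage of their mean — negative when the left-side area
  is larger (asymmetry skewed to the left).  Per-pair Z-tests and
  between-sex Welch t-tests operate on these per-specimen values.
* Mantel correlation between the asymmetric components of two modules:
  Pearson correlation of specimen-by-specimen Euclidean distance matrices,
  permutation p-value, and a bootstrap distribution of r for between-sex
  comparison by a paired t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .io import ModulePartition, PairingScheme
from .procrustes import ShapeComponents

__all__ = [
    "ProcrustesAnovaTable",
    "AsymmetryProfile",
    "MantelResult",
    "procrustes_anova",
    "lr_asym_profile",
    "ztest_profile",
    "compare_profiles_between_sexes",
    "mantel_modules",
    "compare_mantel_distributions",
]


# ---------------------------------------------------------------------------
# Procrustes ANOVA


@dataclass
class ProcrustesAnovaTable:
    rows: pd.DataFrame  # term, df, SS, MS, F, p_rrpp
    permutations: int
    seed: int

    def to_text(self) -> str:
        lines = ["Source of Variation\tdf\tSS\tMS\tF\tp-Value(RRPP)"]
        for _, r in self.rows.iterrows():
            f = "" if np.isnan(r["F"]) else f"{r['F']:.3f}"
            p = "" if np.isnan(r["p_rrpp"]) else f"{r['p_rrpp']:.4f}"
            lines.append(
                f"{r['term']}\t{int(r['df'])}\t{r['SS']:.4g}\t{r['MS']:.4g}\t{f}\t{p}"
            )
        return "\n".join(lines)


def _sequential_ss(q: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Squared norms of the projections of y on each orthonormal column."""
    proj = q.T @ y
    return (proj**2).sum(axis=1)


def procrustes_anova(
    components: ShapeComponents,
    permutations: int = 1000,
    seed: int = 0,
) -> ProcrustesAnovaTable:
    """Two-way Procrustes ANOVA with sex nested in both shape components.

    The response is the stack of aligned originals and mirrored copies,
    one row per specimen-replicate-side.  Sequential (type-I) sums of
    squares are taken for three 1-df terms — sex (symmetric component),
    side (directional asymmetry) and sex x side (the sex contrast in
    fluctuating asymmetry) — with everything else (individual variation,
    individual x side, replicate error) pooled into the error row, whose
    df is ``2nr - 4`` ... i.e. total ``2nr - 1`` minus the three model df.

    RRPP p-values permute reduced-model residuals at the term's
    exchangeable unit: whole-specimen blocks for the sex terms, side
    swaps within specimen-replicate for the side term.
    """
    if components.aligned_original is None:
        raise ValueError("components lack replicate-level aligned copies")
    sexes = {components.sex[components.specimen_ids.index(s)] for s in components.specimen_ids}
    if None in sexes:
        raise ValueError("sex labels are required for the ANOVA")
    reps = {}
    for s in components.record_specimen:
        reps[s] = reps.get(s, 0) + 1
    if min(reps.values()) < 2:
        raise ValueError(
            "at least 2 replicates per specimen are required: the error "
            "term is otherwise undefined"
        )

    n_rec = components.aligned_original.shape[0]
    k2 = components.n_landmarks * 2
    y = np.concatenate(
        [
            components.aligned_original.reshape(n_rec, k2),
            components.aligned_reflected.reshape(n_rec, k2),
        ]
    )
    n_rows = 2 * n_rec

    spec_of_row = components.record_specimen * 2
    side = np.concatenate([np.ones(n_rec), -np.ones(n_rec)])
    sex_of_spec = {
        s: components.sex[components.specimen_ids.index(s)]
        for s in components.specimen_ids
    }
    sex = np.array([1.0 if sex_of_spec[s] == "F" else -1.0 for s in spec_of_row])

    def design_q(sex_col: np.ndarray, side_col: np.ndarray) -> np.ndarray:
        x = np.column_stack(
            [np.ones(n_rows), sex_col, side_col, sex_col * side_col]
        )
        q, _ = np.linalg.qr(x)
        return q

    q = design_q(sex, side)
    ss_seq = _sequential_ss(q, y)  # intercept, sex, side, sex:side
    ss_total = float((y**2).sum()) - ss_seq[0]
    ss_terms = ss_seq[1:]
    ss_err = ss_total - ss_terms.sum()
    df_terms = np.array([1, 1, 1])
    df_err = n_rows - 1 - 3
    ms_terms = ss_terms / df_terms
    ms_err = ss_err / df_err
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = np.where(ms_err > 0, ms_terms / ms_err, np.nan)

    # --- RRPP ------------------------------------------------------------
    rng = np.random.default_rng(seed)
    spec_ids = components.specimen_ids
    n_spec = len(spec_ids)
    rows_of_spec = {s: [] for s in spec_ids}
    for row, s in enumerate(spec_of_row):
        rows_of_spec[s].append(row)
    block_rows = np.array([rows_of_spec[s] for s in spec_ids])  # (n_spec, 2r)
    # rows of the two sides of the same record, for side swaps
    pair_rows = np.column_stack([np.arange(n_rec), np.arange(n_rec) + n_rec])

    counts = np.zeros(3)
    if permutations > 0 and ms_err > 0:
        # reduced-model residuals per term (sequential)
        x_full = np.column_stack([np.ones(n_rows), sex, side, sex * side])
        fits, resids = [], []
        for ncol in (1, 2, 3):  # reduced models for sex, side, sex:side
            xr = x_full[:, :ncol]
            qr_, _ = np.linalg.qr(xr)
            fit = qr_ @ (qr_.T @ y)
            fits.append(fit)
            resids.append(y - fit)

        for _ in range(permutations):
            # sex term: permute whole-specimen residual blocks
            perm = rng.permutation(n_spec)
            ystar = fits[0].copy()
            ystar[block_rows.ravel()] += resids[0][block_rows[perm].ravel()]
            ss_b = _sequential_ss(q, ystar)
            ss_t = float((ystar**2).sum()) - ss_b[0]
            f_b = ss_b[1] / ((ss_t - ss_b[1:].sum()) / df_err)
            if f_b >= f_obs[0] - 1e-12:
                counts[0] += 1

            # side term: randomly swap the two sides of each record
            flips = rng.integers(0, 2, n_rec).astype(bool)
            r1 = resids[1].copy()
            swap = pair_rows[flips]
            r1[swap[:, 0]], r1[swap[:, 1]] = (
                resids[1][swap[:, 1]],
                resids[1][swap[:, 0]],
            )
            ystar = fits[1] + r1
            ss_b = _sequential_ss(q, ystar)
            ss_t = float((ystar**2).sum()) - ss_b[0]
            f_b = ss_b[2] / ((ss_t - ss_b[1:].sum()) / df_err)
            if f_b >= f_obs[1] - 1e-12:
                counts[1] += 1

            # interaction: permute specimen blocks of main-effects residuals
            perm = rng.permutation(n_spec)
            ystar = fits[2].copy()
            ystar[block_rows.ravel()] += resids[2][block_rows[perm].ravel()]
            ss_b = _sequential_ss(q, ystar)
            ss_t = float((ystar**2).sum()) - ss_b[0]
            f_b = ss_b[3] / ((ss_t - ss_b[1:].sum()) / df_err)
            if f_b >= f_obs[2] - 1e-12:
                counts[2] += 1

        p = (counts + 1.0) / (permutations + 1.0)
    else:
        p = np.full(3, np.nan)

    rows = pd.DataFrame(
        {
            "term": [
                "symmetric (sex)",
                "directional_asymmetry (sex)",
                "fluctuating_asymmetry (sex)",
                "error",
            ],
            "df": [1, 1, 1, df_err],
            "SS": [*ss_terms, ss_err],
            "MS": [*ms_terms, ms_err],
            "F": [*f_obs, np.nan],
            "p_rrpp": [*p, np.nan],
        }
    )
    return ProcrustesAnovaTable(rows=rows, permutations=permutations, seed=seed)


# ---------------------------------------------------------------------------
# left-right triangle-area asymmetry profile


@dataclass
class AsymmetryProfile:
    """Per-pair, per-specimen left-right asymmetry percentages.

    ``values`` is (n_specimens, n_pairs) in the scheme's longitudinal
    (anterior-to-posterior) order.  Statistics are filled by
    :func:`ztest_profile`.
    """

    pair_labels: list[str]
    specimen_ids: list[str]
    sex: list[str | None]
    values: np.ndarray
    degenerate: np.ndarray  # bool, same shape as values
    stats: pd.DataFrame | None = None

    def subset_sex(self, sex: str) -> "AsymmetryProfile":
        mask = np.array([s == sex for s in self.sex])
        return AsymmetryProfile(
            pair_labels=self.pair_labels,
            specimen_ids=[s for s, m in zip(self.specimen_ids, mask) if m],
            sex=[s for s, m in zip(self.sex, mask) if m],
            values=self.values[mask],
            degenerate=self.degenerate[mask],
        )


def lr_asym_profile(
    components: ShapeComponents,
    scheme: PairingScheme,
    remove_directional: bool = False,
) -> AsymmetryProfile:
    """Triangle-area left-right asymmetry descriptor per pair and specimen.

    For each bilateral pair, the area of the right triangle whose legs run
    parallel and perpendicular to the symmetry axis from the axis-reference
    landmark to the pair member: ``A = |x_lm - x_ref| * |y_lm - y_ref| / 2``,
    evaluated on the per-specimen aligned configuration (symmetric +
    asymmetric component).  The descriptor is the side difference as a
    percentage of the mean area, ``100 * (A_R - A_L) / ((A_L + A_R) / 2)``:
    negative when the left area is larger.  Pairs where both areas vanish
    are flagged degenerate and reported as 0.

    ``remove_directional`` subtracts each sex's mean asymmetric component
    first, leaving the fluctuating part of the asymmetry.
    """
    configs = components.symmetric + components.asymmetric
    if remove_directional:
        asym = components.asymmetric.copy()
        for sex in sorted({s for s in components.sex if s is not None}):
            mask = components.sex_mask(sex)
            asym[mask] -= asym[mask].mean(axis=0)
        configs = components.symmetric + asym

    ref = scheme.axis_reference - 1
    order = scheme.ordered_pair_positions()
    labels = [scheme.pair_label(pos) for pos in order]
    n = configs.shape[0]
    values = np.zeros((n, len(order)))
    degenerate = np.zeros((n, len(order)), dtype=bool)
    for j, pos in enumerate(order):
        left, right = scheme.pairs[pos - 1]
        dl = np.abs(configs[:, left - 1] - configs[:, ref])
        dr = np.abs(configs[:, right - 1] - configs[:, ref])
        a_l = 0.5 * dl[:, 0] * dl[:, 1]
        a_r = 0.5 * dr[:, 0] * dr[:, 1]
        denom = (a_l + a_r) / 2.0
        zero = denom == 0.0
        degenerate[:, j] = zero
        with np.errstate(divide="ignore", invalid="ignore"):
            values[:, j] = np.where(zero, 0.0, 100.0 * (a_r - a_l) / denom)
    return AsymmetryProfile(
        pair_labels=labels,
        specimen_ids=list(components.specimen_ids),
        sex=list(components.sex),
        values=values,
        degenerate=degenerate,
    )


def ztest_profile(profile: AsymmetryProfile, sigma: float | None = None) -> AsymmetryProfile:
    """One-sample Z-test of each pair's mean descriptor against 0.

    ``z = mean / (sd / sqrt(n))`` with the sample standard deviation as
    sigma unless a fixed ``sigma`` is supplied; two-sided normal p.
    Zero-variance pairs are flagged: p = 0 when the mean is nonzero
    (deterministic departure), p = 1 when the mean is exactly 0.
    """
    v = profile.values
    n = v.shape[0]
    if n < 3:
        raise ValueError("Z-test needs at least 3 specimens")
    mean = v.mean(axis=0)
    sd = np.full(v.shape[1], sigma) if sigma is not None else v.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    z = np.zeros_like(mean)
    p = np.ones_like(mean)
    flag = sd == 0.0
    ok = ~flag
    z[ok] = mean[ok] / se[ok]
    p[ok] = 2.0 * stats.norm.sf(np.abs(z[ok]))
    z[flag & (mean != 0)] = np.inf * np.sign(mean[flag & (mean != 0)])
    p[flag & (mean != 0)] = 0.0
    p[flag & (mean == 0)] = 1.0
    tcrit = stats.norm.ppf(0.975)
    profile.stats = pd.DataFrame(
        {
            "pair": profile.pair_labels,
            "mean": mean,
            "ci_lo": mean - tcrit * se,
            "ci_hi": mean + tcrit * se,
            "z": z,
            "p": p,
            "degenerate": flag,
        }
    )
    return profile


def compare_profiles_between_sexes(
    profile_f: AsymmetryProfile, profile_m: AsymmetryProfile
) -> pd.DataFrame:
    """Per-pair two-sample Welch t-test of the descriptor between sexes.

    Sample sizes differ between sexes, so a literally paired test is not
    possible at the specimen level; Welch's unequal-variance t is used.
    """
    if profile_f.pair_labels != profile_m.pair_labels:
        raise ValueError("profiles cover different pairing schemes")
    if profile_f.values.shape[0] < 2 or profile_m.values.shape[0] < 2:
        raise ValueError("each sex needs at least 2 specimens")
    t, p = stats.ttest_ind(
        profile_f.values, profile_m.values, axis=0, equal_var=False
    )
    return pd.DataFrame(
        {
            "pair": profile_f.pair_labels,
            "mean_F": profile_f.values.mean(axis=0),
            "mean_M": profile_m.values.mean(axis=0),
            "t": t,
            "p": p,
        }
    )


# ---------------------------------------------------------------------------
# Mantel correlation of module asymmetries


@dataclass
class MantelResult:
    r_point: float
    r_distribution: np.ndarray
    p_perm: float
    iterations: int
    permutations: int
    seed: int


def _module_columns(partition: ModulePartition, label: str) -> np.ndarray:
    lms = np.array(partition.landmarks_in(label)) - 1
    return np.sort(np.concatenate([2 * lms, 2 * lms + 1]))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0.0:
        return 0.0
    return float((a * b).sum() / denom)


def mantel_modules(
    components: ShapeComponents,
    partition: ModulePartition,
    iterations: int = 5000,
    permutations: int = 999,
    seed: int = 0,
    sex: str | None = None,
) -> MantelResult:
    """Mantel correlation between two modules' asymmetric components.

    Specimen-by-specimen Euclidean distance matrices are built from each
    module's asymmetric Procrustes coordinates; ``r_point`` is the Pearson
    correlation of their lower triangles.  The p-value comes from
    row/column permutations of one matrix; ``r_distribution`` from
    bootstrap resampling of specimens (both matrices recomputed per
    resample), for the between-sex distribution comparison.
    """
    if partition.module_count != 2:
        raise ValueError(
            "Mantel correlation is defined between exactly 2 modules; "
            "run pairwise over a multi-module partition"
        )
    x = components.flat_asymmetric()
    if sex is not None:
        x = x[components.sex_mask(sex)]
    n = x.shape[0]
    if n < 5:
        raise ValueError("need at least 5 specimens")
    la, lb = partition.module_labels
    xa = x[:, _module_columns(partition, la)]
    xb = x[:, _module_columns(partition, lb)]
    da, db = pdist(xa), pdist(xb)
    r_point = _pearson(da, db)

    rng = np.random.default_rng(seed)
    db_sq = squareform(db)
    iu = np.triu_indices(n, 1)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        r_b = _pearson(da, db_sq[np.ix_(perm, perm)][iu])
        if r_b >= r_point - 1e-12:
            count += 1
    p_perm = (count + 1.0) / (permutations + 1.0)

    r_dist = np.zeros(iterations)
    for b in range(iterations):
        idx = rng.integers(0, n, n)
        r_dist[b] = _pearson(pdist(xa[idx]), pdist(xb[idx]))

    return MantelResult(
        r_point=r_point,
        r_distribution=r_dist,
        p_perm=p_perm,
        iterations=iterations,
        permutations=permutations,
        seed=seed,
    )


def compare_mantel_distributions(
    result_f: MantelResult, result_m: MantelResult
) -> tuple[float, float]:
    """Paired t-test over two bootstrap r distributions (by iteration index)."""
    if result_f.iterations != result_m.iterations:
        raise ValueError("iteration counts differ; distributions cannot be paired")
    diff = result_f.r_distribution - result_m.r_distribution
    if np.allclose(diff.std(ddof=1), 0.0):
        warnings.warn(
            "degenerate comparison: constant difference between distributions",
            stacklevel=2,
        )
        if np.allclose(diff.mean(), 0.0):
            return 0.0, 1.0
        return float(np.sign(diff.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(result_f.r_distribution, result_m.r_distribution)
    return float(t), float(p)
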
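"""Procrustes superimposition and bilateral-symmetry decomposition.

Implements generalized Procrustes analysis (GPA) with generalized
least-squares fitting, and the object-symmetry decomposition: every
configuration is compared with its mirrored, label-swapped copy after a
joint superimposition, splitting shape variation into a symmetric component
(the average of the two copies) and an asymmetric component (half their
difference, so that aligned original = symmetric + asymmetric exactly).

Conventions
-----------
* Reflection is across the x-axis; after a symmetric superimposition the
  consensus has its midline landmarks exactly on the x-axis, with the
  anterior axis-reference landmark at positive x.
* Rotations fitted during GPA are proper (determinant +1); reflection is
  handled only by the explicit reflect-relabel map.
* Configurations are scaled to unit centroid size (full Procrustes fit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import LandmarkDataset, PairingScheme, StructureError

__all__ = [
    "ShapeComponents",
    "centroid_size",
    "reflect_relabel",
    "gpa_align",
    "decompose_symmetry",
    "regress_out_size",
]

GPA_TOL = 1e-10
GPA_MAX_ITER = 100


def centroid_size(config: np.ndarray) -> float:
    """Root summed squared distances of the landmarks from their centroid.

    The standard geometric-morphometrics size measure: invariant to
    translation and rotation, linear under isotropic scaling.
    """
    config = np.asarray(config, dtype=float)
    if config.ndim != 2 or config.shape[0] < 2:
        raise ValueError("configuration must be K x d with K >= 2")
    if not np.isfinite(config).all():
        raise ValueError("non-finite coordinates")
    centered = config - config.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs == 0.0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return cs


def reflect_relabel(config: np.ndarray, scheme: PairingScheme) -> np.ndarray:
    """Mirror a configuration across the x-axis and swap left/right labels.

    Midline landmarks keep their labels.  The map is an involution; a
    perfectly symmetric configuration (midline on the x-axis, pairs
    mirrored) is a fixed point.
    """
    config = np.asarray(config, dtype=float)
    if config.shape != (scheme.n_landmarks, 2):
        raise StructureError(
            f"configuration shape {config.shape} does not match scheme "
            f"with K={scheme.n_landmarks}"
        )
    mirrored = config * np.array([1.0, -1.0])
    return mirrored[scheme.relabel_permutation()]


def _optimal_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||x @ R - target||_F (det(R) = +1)."""
    h = x.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def _center_scale(config: np.ndarray) -> np.ndarray:
    centered = config - config.mean(axis=0)
    return centered / centroid_size(config)


def _axis_rotation(mean: np.ndarray, scheme: PairingScheme) -> np.ndarray:
    """Rotation placing the midline best-fit line on the x-axis.

    The anterior axis-reference landmark ends at positive x.
    """
    mid = mean[scheme.midline_idx()]
    mid_c = mid - mid.mean(axis=0)
    # principal direction of the midline scatter
    _, _, vt = np.linalg.svd(mid_c, full_matrices=False)
    direction = vt[0]
    c, s = direction / np.hypot(*direction)
    rot = np.array([[c, -s], [s, c]])  # maps `direction` onto (1, 0)
    ref = mean[scheme.axis_reference - 1] @ rot
    if ref[0] < 0:
        rot = rot @ np.array([[-1.0, 0.0], [0.0, -1.0]])
    return rot


@dataclass
class ShapeComponents:
    """Symmetric/asymmetric shape decomposition of a landmark dataset.

    Replicate-level aligned copies are retained (for the ANOVA error term)
    alongside the replicate-averaged per-specimen components.
    """

    specimen_ids: list[str]
    sex: list[str | None]                 # per specimen
    symmetric: np.ndarray                 # (n, K, 2) replicate-averaged
    asymmetric: np.ndarray                # (n, K, 2) replicate-averaged
    centroid_sizes: np.ndarray            # (n,) original units
    grand_mean: np.ndarray                # (K, 2), unit centroid size
    scheme: PairingScheme
    # replicate-level quantities, one entry per specimen x replicate
    record_specimen: list[str] = field(default_factory=list)
    record_replicate: list[int] = field(default_factory=list)
    aligned_original: np.ndarray | None = None   # (n_rec, K, 2)
    aligned_reflected: np.ndarray | None = None  # (n_rec, K, 2)
    alignment_meta: dict = field(default_factory=dict)

    @property
    def n_specimens(self) -> int:
        return len(self.specimen_ids)

    @property
    def n_landmarks(self) -> int:
        return self.grand_mean.shape[0]

    def sex_mask(self, sex: str) -> np.ndarray:
        return np.array([s == sex for s in self.sex])

    def flat_symmetric(self) -> np.ndarray:
        """Symmetric component as an (n, 2K) matrix (lm1_x, lm1_y, ...)."""
        return self.symmetric.reshape(self.n_specimens, -1)

    def flat_asymmetric(self) -> np.ndarray:
        return self.asymmetric.reshape(self.n_specimens, -1)


def gpa_align(
    configs: np.ndarray,
    scheme: PairingScheme | None = None,
    include_reflections: bool = False,
    fit_scale: bool = True,
    tol: float = GPA_TOL,
    max_iter: int = GPA_MAX_ITER,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Generalized Procrustes alignment of a stack of configurations.

    Each configuration is centred, scaled to unit centroid size and then
    refitted to the iteratively updated consensus by a proper rotation
    plus (with ``fit_scale``, the full Procrustes fit) an optimal scale
    factor; the consensus is renormalized to unit centroid size each
    iteration.  With ``include_reflections`` the reflect-relabel copy of
    every configuration joins the alignment set and the consensus is
    symmetrized each iteration — the object-symmetry superimposition: the
    aligned stack then holds ``2*m`` configurations, originals first,
    mirrored copies second, in matching order.

    Returns ``(aligned, mean, meta)``.
    """
    configs = np.asarray(configs, dtype=float)
    if configs.ndim != 3 or configs.shape[2] != 2:
        raise ValueError("expected an (m, K, 2) stack of configurations")
    if configs.shape[0] < 2 and not include_reflections:
        raise ValueError("GPA needs at least 2 configurations")
    if include_reflections and scheme is None:
        raise ValueError("include_reflections requires a pairing scheme")

    base = np.stack([_center_scale(c) for c in configs])
    if include_reflections:
        perm = scheme.relabel_permutation()
        mirrored = (base * np.array([1.0, -1.0]))[:, perm, :]
        base = np.concatenate([base, mirrored])

    mean = base[0].copy()
    if include_reflections:
        refl = (mean * np.array([1.0, -1.0]))[perm]
        mean = _center_scale((mean + refl) / 2.0)
    work = base.copy()
    delta, iterations = np.inf, 0
    objective: list[float] = []
    for iterations in range(1, max_iter + 1):
        for i in range(base.shape[0]):
            rotated = base[i] @ _optimal_rotation(base[i], mean)
            if fit_scale:
                rotated = rotated * float((rotated * mean).sum())
            work[i] = rotated
        objective.append(float(((work - mean) ** 2).sum()))
        new_mean = work.mean(axis=0)
        if include_reflections:
            refl = (new_mean * np.array([1.0, -1.0]))[perm]
            new_mean = (new_mean + refl) / 2.0
        new_mean = _center_scale(new_mean)
        delta = float(np.sqrt(((new_mean - mean) ** 2).sum()))
        mean = new_mean
        if delta < tol:
            break
    else:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations "
            f"(last delta {delta:.3e})",
            stacklevel=2,
        )

    if scheme is not None:
        rot = _axis_rotation(mean, scheme)
        mean = mean @ rot
        work = work @ rot

    meta = {
        "iterations": iterations,
        "delta": delta,
        "objective_history": objective,
        "include_reflections": include_reflections,
        "axis_aligned": scheme is not None,
    }
    return work, mean, meta


def decompose_symmetry(
    dataset: LandmarkDataset, scheme: PairingScheme
) -> ShapeComponents:
    """Object-symmetry decomposition of a replicated landmark dataset.

    A joint GPA is run over all originals and their reflect-relabel copies
    (``2 * n * r`` configurations).  Per specimen-replicate the symmetric
    component is the average of the aligned original and its aligned
    mirrored copy, and the asymmetric component is half their difference.
    Per-specimen components average over replicates.
    """
    dataset.validate()
    if not dataset.records:
        raise StructureError("empty dataset")
    if scheme.n_landmarks != dataset.n_landmarks:
        raise StructureError(
            f"scheme has K={scheme.n_landmarks} but dataset has "
            f"K={dataset.n_landmarks}"
        )

    configs = dataset.coords_array()
    aligned, mean, meta = gpa_align(configs, scheme, include_reflections=True)
    n_rec = configs.shape[0]
    orig, refl = aligned[:n_rec], aligned[n_rec:]
    sym_rep = (orig + refl) / 2.0
    asym_rep = (orig - refl) / 2.0

    spec_ids = dataset.specimen_ids
    index = {s: i for i, s in enumerate(spec_ids)}
    k = dataset.n_landmarks
    n = len(spec_ids)
    sym = np.zeros((n, k, 2))
    asym = np.zeros((n, k, 2))
    sizes = np.zeros(n)
    counts = np.zeros(n)
    sex: list[str | None] = [None] * n
    rec_spec: list[str] = []
    rec_rep: list[int] = []
    for j, r in enumerate(dataset.records):
        i = index[r.specimen_id]
        sym[i] += sym_rep[j]
        asym[i] += asym_rep[j]
        raw = r.coords * (r.scale if r.scale is not None else 1.0)
        sizes[i] += centroid_size(raw)
        counts[i] += 1
        sex[i] = r.sex
        rec_spec.append(r.specimen_id)
        rec_rep.append(r.replicate)
    sym /= counts[:, None, None]
    asym /= counts[:, None, None]
    sizes /= counts

    return ShapeComponents(
        specimen_ids=spec_ids,
        sex=sex,
        symmetric=sym,
        asymmetric=asym,
        centroid_sizes=sizes,
        grand_mean=mean,
        scheme=scheme,
        record_specimen=rec_spec,
        record_replicate=rec_rep,
        aligned_original=orig,
        aligned_reflected=refl,
        alignment_meta=meta,
    )


def regress_out_size(
    components: ShapeComponents, log_size: bool = False
) -> np.ndarray:
    """Residuals of the symmetric shape coordinates regressed on size.

    Multivariate least squares of the flattened symmetric component
    (n x 2K) on centroid size with an intercept; ``log_size`` switches the
    predictor to log centroid size.  Residual columns have mean zero and
    zero sample covariance with the predictor.
    """
    y = components.flat_symmetric()
    n = y.shape[0]
    if n < 3:
        raise ValueError("size regression needs at least 3 specimens")
    size = components.centroid_sizes.astype(float)
    if log_size:
        size = np.log(size)
    if np.ptp(size) == 0.0:
        warnings.warn(
            "centroid size is constant; returning centred coordinates",
            stacklevel=2,
        )
        return y - y.mean(axis=0)
    x = np.column_stack([np.ones(n), size])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta
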
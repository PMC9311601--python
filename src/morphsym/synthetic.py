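"""Synthetic landmark data with known symmetry and modularity structure.

Emulates the sampling design of a bilateral-symmetry study on a dorsally
digitized crustacean cephalothorax: two sexes of unequal sample size, two
digitization replicates per specimen, block-structured shape covariance
(stronger correlation within than between developmental modules),
sex-specific directional asymmetry, individual fluctuating asymmetry whose
module-wise components can be correlated, digitization noise, and an
arbitrary similarity transform per digitized copy so that the Procrustes
stage is genuinely exercised.

Every drawn effect is returned in a truth record so downstream estimators
can be tested for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import (
    LandmarkDataset,
    LandmarkRecord,
    ModulePartition,
    PairingScheme,
)
from .procrustes import centroid_size, reflect_relabel

__all__ = [
    "SyntheticParams",
    "make_scheme",
    "make_template",
    "generate_dataset",
    "generate_shape_matrix",
]


def make_scheme(n_pairs: int, n_midline: int = 2) -> PairingScheme:
    """A generic pairing scheme for small test geometries.

    Midline landmarks are ``1..M``, right-side landmarks ``M+1..M+P``,
    left-side landmarks ``M+P+1..M+2P``; pair p is ``(M+P+p, M+p)``.
    """
    m = n_midline
    pairs = tuple((m + n_pairs + p, m + p) for p in range(1, n_pairs + 1))
    return PairingScheme(
        pairs=pairs,
        midline=tuple(range(1, m + 1)),
        axis_reference=1,
        longitudinal_order=tuple(range(1, n_pairs + 1)),
    )


def make_template(scheme: PairingScheme) -> np.ndarray:
    """Deterministic bilaterally symmetric template configuration.

    Midline landmarks sit on the x-axis (axis-reference landmark
    anterior-most, at the largest x); paired landmarks mirror across it,
    arranged anterior-to-posterior in the scheme's longitudinal order with
    a smoothly varying half-width, loosely evoking a carapace outline.
    The output is centred with unit centroid size.
    """
    k = scheme.n_landmarks
    coords = np.zeros((k, 2))
    p = scheme.n_pairs
    order = scheme.ordered_pair_positions()
    xs = np.linspace(0.9, -0.9, p)
    u = np.linspace(0.12, 0.88, p)
    ys = 0.25 + 0.4 * np.sin(np.pi * u)
    for rank, pos in enumerate(order):
        left, right = scheme.pairs[pos - 1]
        coords[left - 1] = (xs[rank], ys[rank])
        coords[right - 1] = (xs[rank], -ys[rank])
    mid = list(scheme.midline)
    mid.remove(scheme.axis_reference)
    coords[scheme.axis_reference - 1] = (1.1, 0.0)
    for j, lm in enumerate(sorted(mid)):
        coords[lm - 1] = (0.6 - 1.7 * (j + 1) / (len(mid) + 1), 0.0)
    coords -= coords.mean(axis=0)
    coords /= centroid_size(coords)
    assert np.allclose(reflect_relabel(coords, scheme), coords, atol=1e-12)
    return coords


@dataclass
class SyntheticParams:
    """Generator settings; defaults mirror the emulated study design.

    55 females and 48 males digitized twice; shape deviations with
    exchangeable block correlation (``rho_within`` inside a developmental
    module, ``rho_between`` across); directional asymmetry added to the
    left side with the female vector pushing the left margin outward and
    the male vector inward (opposite skews, as in sexually dimorphic
    carapaces); fluctuating asymmetry equicorrelated across coordinates at
    ``asym_module_corr`` (so module-wise asymmetries correlate); and
    digitization noise per replicate.  All SDs are in units of the
    unit-centroid-size template.
    """

    n_female: int = 55
    n_male: int = 48
    replicates: int = 2
    rho_within: float = 0.5
    rho_between: float = 0.2
    sigma_shape: float = 0.02
    da_magnitude_by_sex: dict[str, float] = field(
        default_factory=lambda: {"F": 0.012, "M": -0.009}
    )
    da_vector_by_sex: dict[str, np.ndarray] | None = None  # (K, 2) per sex
    sigma_fa: float = 0.01
    sigma_digit: float = 0.004
    asym_module_corr: float = 0.5
    base_size: float = 10.0  # mean digitized centroid size, arbitrary units
    seed: int = 0


def _block_correlation(
    slot_modules: np.ndarray, rho_within: float, rho_between: float
) -> np.ndarray:
    """Exchangeable within/between-block correlation, shrunk to PSD."""
    same = slot_modules[:, None] == slot_modules[None, :]
    r = np.where(same, rho_within, rho_between)
    np.fill_diagonal(r, 1.0)
    w = np.linalg.eigvalsh(r)
    if w[0] < 1e-10:
        lam = (1e-8 - w[0]) / (1.0 - w[0])
        r = (1 - lam) * r + lam * np.eye(len(r))
        if np.linalg.eigvalsh(r)[0] < 0:
            raise ValueError("correlation matrix not PSD after shrinkage")
    return r


def _default_da_vector(
    scheme: PairingScheme, template: np.ndarray, magnitude: float
) -> np.ndarray:
    """Directional asymmetry: displace left landmarks along the outward
    normal (away from the symmetry axis) by ``magnitude``."""
    da = np.zeros_like(template)
    li = scheme.left_idx()
    outward = np.sign(template[li, 1])
    outward[outward == 0] = 1.0
    da[li, 1] = magnitude * outward
    return da


def generate_shape_matrix(
    n: int,
    partition: ModulePartition,
    rho_within: float,
    rho_between: float,
    sigma: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Draw an (n, 2K) shape matrix with landmark-level block correlation.

    Landmarks correlate at ``rho_within`` inside a module and
    ``rho_between`` across modules; a landmark's x and y coordinates are
    independent.  Landmarks are exchangeable under the block structure,
    which makes this the reference input for calibrating the modularity
    statistics (the symmetric component of real bilateral data is *not*
    landmark-exchangeable: pair members mirror each other).
    """
    rng = np.random.default_rng(seed)
    labels = partition.labels_array()
    corr = _block_correlation(labels, rho_within, rho_between)
    chol = np.linalg.cholesky(corr)
    k = len(labels)
    x = sigma * rng.standard_normal((n, k)) @ chol.T
    y = sigma * rng.standard_normal((n, k)) @ chol.T
    out = np.empty((n, 2 * k))
    out[:, 0::2] = x
    out[:, 1::2] = y
    return out


def generate_dataset(
    params: SyntheticParams,
    scheme: PairingScheme,
    partition: ModulePartition | None = None,
    template: np.ndarray | None = None,
) -> tuple[LandmarkDataset, dict]:
    """Draw a replicated two-sex landmark dataset; returns (dataset, truth).

    ``partition`` supplies the module structure driving the block
    covariance and the module-wise asymmetry correlation; when omitted the
    whole configuration is one block.  Asymmetry is injected in the
    template's symmetric frame *before* the per-copy random similarity
    transform, so recovering it requires the Procrustes machinery to undo
    rotation, scale and translation.
    """
    rng = np.random.default_rng(params.seed)
    k = scheme.n_landmarks
    if template is None:
        template = make_template(scheme)
    if template.shape != (k, 2):
        raise ValueError("template does not match the pairing scheme")

    # symmetric deviations are drawn per "slot": one per bilateral pair
    # (expanded mirror-symmetrically) plus one per midline landmark
    # (x displacement only, so individuals stay exactly symmetric).
    p, mids = scheme.n_pairs, list(scheme.midline)
    n_slots = p + len(mids)
    if partition is not None:
        pair_mod = np.array(
            [partition.assignment[scheme.pairs[i][0]] for i in range(p)]
        )
        mid_mod = np.array([partition.assignment[m] for m in mids])
        slot_modules = np.concatenate([pair_mod, mid_mod])
    else:
        slot_modules = np.array(["all"] * n_slots)
    corr = _block_correlation(slot_modules, params.rho_within, params.rho_between)
    chol = np.linalg.cholesky(corr)

    da_by_sex: dict[str, np.ndarray] = {}
    for sex in ("F", "M"):
        if params.da_vector_by_sex is not None:
            da_by_sex[sex] = np.asarray(params.da_vector_by_sex[sex], dtype=float)
        else:
            da_by_sex[sex] = _default_da_vector(
                scheme, template, params.da_magnitude_by_sex.get(sex, 0.0)
            )

    li, ri, mi = scheme.left_idx(), scheme.right_idx(), scheme.midline_idx()
    a = params.asym_module_corr
    specimens = [("F", i + 1) for i in range(params.n_female)] + [
        ("M", i + 1) for i in range(params.n_male)
    ]

    records: list[LandmarkRecord] = []
    truth = {
        "specimen_ids": [],
        "sex": [],
        "sym_dev_x": np.zeros((len(specimens), n_slots)),
        "sym_dev_y": np.zeros((len(specimens), n_slots)),
        "fa_left": np.zeros((len(specimens), p, 2)),
        "fa_factor": np.zeros(len(specimens)),
        "slot_modules": slot_modules,
        "da_vector_by_sex": da_by_sex,
        "template": template,
    }
    for s, (sex, num) in enumerate(specimens):
        sid = f"{sex}{num:03d}"
        dev_x = params.sigma_shape * (chol @ rng.standard_normal(n_slots))
        dev_y = params.sigma_shape * (chol @ rng.standard_normal(n_slots))
        config = template.copy()
        config[li, 0] += dev_x[:p]
        config[ri, 0] += dev_x[:p]
        config[li, 1] += dev_y[:p]
        config[ri, 1] -= dev_y[:p]
        config[mi, 0] += dev_x[p:]

        config[li] += da_by_sex[sex][li]

        g = rng.standard_normal()
        eps = rng.standard_normal((p, 2))
        fa = params.sigma_fa * (np.sqrt(a) * g + np.sqrt(1.0 - a) * eps)
        config[li] += fa

        truth["specimen_ids"].append(sid)
        truth["sex"].append(sex)
        truth["sym_dev_x"][s] = dev_x
        truth["sym_dev_y"][s] = dev_y
        truth["fa_left"][s] = fa
        truth["fa_factor"][s] = g

        for rep in range(1, params.replicates + 1):
            digitized = config + params.sigma_digit * rng.standard_normal((k, 2))
            theta = rng.uniform(0.0, 2.0 * np.pi)
            c, si_ = np.cos(theta), np.sin(theta)
            rot = np.array([[c, -si_], [si_, c]])
            scale = params.base_size * np.exp(0.05 * rng.standard_normal())
            shift = rng.uniform(-5.0, 5.0, size=2)
            digitized = scale * (digitized @ rot) + shift
            records.append(
                LandmarkRecord(
                    specimen_id=sid, sex=sex, replicate=rep, coords=digitized
                )
            )

    dataset = LandmarkDataset(records)
    dataset.validate(require_sex=True)
    return dataset, truth
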
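"""Landmark data and configuration I/O.

Reads and writes TPS landmark files (the tpsDig2 line-oriented dialect),
sidecar specimen metadata (CSV), and the analysis configuration (YAML)
describing the bilateral pairing scheme and the modularity hypotheses.

All landmark indices in configuration files, reports and error messages are
1-based, matching how pairs are labelled in the morphometric literature
(e.g. "pair 26-04").  Internal arrays are 0-based; every public interface
speaks 1-based.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "LandmarkRecord",
    "LandmarkDataset",
    "PairingScheme",
    "ModulePartition",
    "TpsParseError",
    "StructureError",
    "ConfigError",
    "read_tps",
    "write_tps",
    "read_metadata",
    "write_metadata",
    "load_analysis_config",
    "default_config_path",
]


class TpsParseError(ValueError):
    """A TPS block could not be parsed; the message names the block."""


class StructureError(ValueError):
    """Dataset-level inconsistency (e.g. differing landmark counts)."""


class ConfigError(ValueError):
    """Invalid pairing-scheme or partition configuration."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class LandmarkRecord:
    specimen_id: str
    sex: str | None  # "F" / "M" / None when no metadata joined yet
    replicate: int
    coords: np.ndarray  # (K, 2) float
    scale: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise StructureError(
                f"specimen {self.specimen_id!r}: coordinates must be K x 2, "
                f"got shape {self.coords.shape}"
            )
        if not np.isfinite(self.coords).all():
            raise StructureError(
                f"specimen {self.specimen_id!r}: non-finite coordinate"
            )
        if self.scale is not None and not self.scale > 0:
            raise StructureError(
                f"specimen {self.specimen_id!r}: scale must be positive"
            )


@dataclass
class LandmarkDataset:
    """A set of digitized 2D landmark configurations.

    Each specimen appears once per digitization replicate; all
    configurations share the same landmark count K.
    """

    records: list[LandmarkRecord] = field(default_factory=list)

    @property
    def n_landmarks(self) -> int:
        if not self.records:
            return 0
        return self.records[0].coords.shape[0]

    @property
    def specimen_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.specimen_id, None)
        return list(seen)

    @property
    def n_specimens(self) -> int:
        return len(self.specimen_ids)

    @property
    def n_replicates(self) -> int:
        counts = self._replicate_counts()
        return next(iter(counts.values())) if counts else 0

    def _replicate_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.specimen_id] = counts.get(r.specimen_id, 0) + 1
        return counts

    def sex_of(self, specimen_id: str) -> str | None:
        for r in self.records:
            if r.specimen_id == specimen_id:
                return r.sex
        raise KeyError(specimen_id)

    def validate(self, require_sex: bool = False) -> None:
        if not self.records:
            return
        k = self.records[0].coords.shape[0]
        for r in self.records:
            if r.coords.shape[0] != k:
                raise StructureError(
                    f"specimen {r.specimen_id!r} has {r.coords.shape[0]} "
                    f"landmarks, expected {k}"
                )
        counts = self._replicate_counts()
        if len(set(counts.values())) > 1:
            raise StructureError(
                "specimens differ in replicate count: "
                + ", ".join(f"{s}={c}" for s, c in sorted(counts.items()))
            )
        if require_sex:
            for r in self.records:
                if r.sex not in ("F", "M"):
                    raise StructureError(
                        f"specimen {r.specimen_id!r}: sex must be 'F' or 'M', "
                        f"got {r.sex!r}"
                    )

    def coords_array(self) -> np.ndarray:
        """All configurations stacked, shape (n_records, K, 2), file order."""
        return np.stack([r.coords for r in self.records])

    def subset(self, specimen_ids: list[str]) -> "LandmarkDataset":
        keep = set(specimen_ids)
        return LandmarkDataset(
            [r for r in self.records if r.specimen_id in keep]
        )


@dataclass(frozen=True)
class PairingScheme:
    """Bilateral pairing of landmarks under object symmetry.

    ``pairs`` lists (left, right) landmark indices, 1-based; ``midline``
    lists the unpaired landmarks on the symmetry axis.  ``axis_reference``
    is the midline landmark anchoring the left-right triangle construction
    (the anterior-most axis point).  ``longitudinal_order`` permutes pair
    positions (1-based into ``pairs``) from anterior to posterior.
    """

    pairs: tuple[tuple[int, int], ...]
    midline: tuple[int, ...]
    axis_reference: int
    longitudinal_order: tuple[int, ...]

    def __post_init__(self) -> None:
        k = self.n_landmarks
        flat = [i for p in self.pairs for i in p] + list(self.midline)
        if len(set(flat)) != len(flat):
            raise ConfigError("pairs and midline overlap or repeat a landmark")
        if sorted(flat) != list(range(1, k + 1)):
            raise ConfigError(
                f"pairs + midline must cover 1..{k} exactly, got {sorted(flat)}"
            )
        if self.axis_reference not in self.midline:
            raise ConfigError("axis_reference must be a midline landmark")
        if sorted(self.longitudinal_order) != list(
            range(1, len(self.pairs) + 1)
        ):
            raise ConfigError(
                "longitudinal_order must be a permutation of pair positions"
            )

    @property
    def n_landmarks(self) -> int:
        return 2 * len(self.pairs) + len(self.midline)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pair_label(self, position: int) -> str:
        """Label of the pair at 1-based ``position``, e.g. ``"26-04"``."""
        left, right = self.pairs[position - 1]
        return f"{left:02d}-{right:02d}"

    # 0-based helpers for numerical code -----------------------------------

    def left_idx(self) -> np.ndarray:
        return np.array([p[0] - 1 for p in self.pairs])

    def right_idx(self) -> np.ndarray:
        return np.array([p[1] - 1 for p in self.pairs])

    def midline_idx(self) -> np.ndarray:
        return np.array([m - 1 for m in self.midline])

    def relabel_permutation(self) -> np.ndarray:
        """0-based row permutation swapping left and right landmarks."""
        perm = np.arange(self.n_landmarks)
        li, ri = self.left_idx(), self.right_idx()
        perm[li], perm[ri] = ri, li
        return perm

    def ordered_pair_positions(self) -> list[int]:
        """Pair positions (1-based) in anterior-to-posterior order."""
        return list(self.longitudinal_order)


@dataclass(frozen=True)
class ModulePartition:
    """Named assignment of landmarks (1-based) to modules."""

    name: str
    assignment: dict[int, str]

    def __post_init__(self) -> None:
        k = len(self.assignment)
        if sorted(self.assignment) != list(range(1, k + 1)):
            raise ConfigError(
                f"partition {self.name!r}: landmarks must be exactly 1..{k}"
            )
        for label in self.module_labels:
            if len(self.landmarks_in(label)) < 2:
                raise ConfigError(
                    f"partition {self.name!r}: module {label!r} has fewer "
                    "than 2 landmarks"
                )

    @property
    def n_landmarks(self) -> int:
        return len(self.assignment)

    @property
    def module_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for i in sorted(self.assignment):
            seen.setdefault(self.assignment[i], None)
        return list(seen)

    @property
    def module_count(self) -> int:
        return len(self.module_labels)

    def landmarks_in(self, label: str) -> list[int]:
        return [i for i in sorted(self.assignment) if self.assignment[i] == label]

    def labels_array(self) -> np.ndarray:
        """Module label per landmark, 0-based landmark order."""
        return np.array(
            [self.assignment[i] for i in range(1, self.n_landmarks + 1)]
        )

    def relabeled(self, labels: np.ndarray, name: str | None = None) -> "ModulePartition":
        """New partition with the given per-landmark label vector."""
        return ModulePartition(
            name or self.name,
            {i + 1: str(lab) for i, lab in enumerate(labels)},
        )


# ---------------------------------------------------------------------------
# TPS I/O


def _parse_id(raw_id: str) -> tuple[str, int]:
    """Split ``<specimen>_r<rep>`` into (specimen_id, replicate)."""
    if "_r" in raw_id:
        stem, _, rep = raw_id.rpartition("_r")
        if rep.isdigit():
            return stem, int(rep)
    return raw_id, 1


def read_tps(path: str | Path, metadata: str | Path | None = None) -> LandmarkDataset:
    """Read a TPS landmark file into a :class:`LandmarkDataset`.

    The accepted dialect is the tpsDig2 one: ``LM=``, coordinate lines,
    optional ``IMAGE=``, ``ID=`` and ``SCALE=`` keys.  ``CURVES=`` /
    ``POINTS=`` sections are skipped with a warning.  Specimen identity and
    replicate come from the ``ID=`` value using the ``<id>_r<n>`` naming
    convention; sex is joined from the sidecar ``metadata`` CSV
    (columns ``specimen_id,sex``) when given.
    """
    path = Path(path)
    sex_by_id: dict[str, str] = {}
    if metadata is not None:
        sex_by_id = read_metadata(metadata)

    records: list[LandmarkRecord] = []
    lines = path.read_text().splitlines()
    i, block = 0, 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TpsParseError(
                f"{path.name}, line {i + 1}: expected LM= to open block "
                f"{block + 1}, got {line!r}"
            )
        block += 1
        try:
            lm_count = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TpsParseError(
                f"{path.name}, block {block}: bad LM count {line!r}"
            ) from exc
        i += 1
        coords = []
        for j in range(lm_count):
            if i >= len(lines):
                raise TpsParseError(
                    f"{path.name}, block {block}: LM={lm_count} but only "
                    f"{j} coordinate lines"
                )
            parts = lines[i].split()
            if len(parts) == 3:
                raise StructureError(
                    f"{path.name}, block {block}: 3 coordinate columns "
                    "(this reader accepts 2D landmarks only)"
                )
            if len(parts) != 2:
                raise TpsParseError(
                    f"{path.name}, block {block}, line {i + 1}: expected "
                    f"2 coordinates, got {lines[i]!r}"
                )
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise TpsParseError(
                    f"{path.name}, block {block}, line {i + 1}: "
                    f"non-numeric coordinate {lines[i]!r}"
                ) from exc
            i += 1
        raw_id, scale = f"spec{block}", None
        while i < len(lines) and lines[i].strip() and "=" in lines[i] and not lines[
            i
        ].strip().upper().startswith("LM="):
            key, _, value = lines[i].strip().partition("=")
            key = key.upper()
            if key == "ID":
                raw_id = value.strip()
            elif key == "IMAGE":
                if raw_id == f"spec{block}":
                    raw_id = Path(value.strip()).stem
            elif key == "SCALE":
                scale = float(value)
            elif key in ("CURVES", "POINTS"):
                warnings.warn(
                    f"{path.name}, block {block}: ignoring {key} section",
                    stacklevel=2,
                )
            i += 1
        specimen_id, replicate = _parse_id(raw_id)
        records.append(
            LandmarkRecord(
                specimen_id=specimen_id,
                sex=sex_by_id.get(specimen_id),
                replicate=replicate,
                coords=np.array(coords),
                scale=scale,
            )
        )

    ds = LandmarkDataset(records)
    ds.validate()
    return ds


def write_tps(dataset: LandmarkDataset, path: str | Path) -> Path:
    """Write the dataset as canonical TPS blocks (6-decimal coordinates)."""
    dataset.validate()
    path = Path(path)
    out: list[str] = []
    for r in dataset.records:
        out.append(f"LM={r.coords.shape[0]}")
        for x, y in r.coords:
            out.append(f"{x:.6f} {y:.6f}")
        out.append(f"ID={r.specimen_id}_r{r.replicate}")
        if r.scale is not None:
            out.append(f"SCALE={r.scale:.6f}")
    path.write_text("\n".join(out) + ("\n" if out else ""))
    return path


def read_metadata(path: str | Path) -> dict[str, str]:
    """Read the sidecar CSV mapping specimen_id to sex."""
    sex_by_id: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            sex_by_id[row["specimen_id"]] = row["sex"]
    return sex_by_id


def write_metadata(dataset: LandmarkDataset, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["specimen_id", "sex", "replicate"])
        for r in dataset.records:
            w.writerow([r.specimen_id, r.sex or "", r.replicate])
    return path


# ---------------------------------------------------------------------------
# analysis configuration


def default_config_path() -> Path:
    """Path of the shipped cephalothorax analysis configuration."""
    return Path(__file__).parent / "data" / "cephalothorax.yaml"


def load_analysis_config(
    path: str | Path | None = None,
) -> tuple[PairingScheme, list[ModulePartition]]:
    """Load pairing scheme and modularity hypotheses from a YAML config.

    Schema::

        landmarks: <K>
        pairs: [[left, right], ...]        # 1-based
        midline: [i, j, ...]
        axis_reference: <midline landmark>
        longitudinal_order: [p1, p2, ...]  # 1-based pair positions
        partitions:
          <name>:
            <module-label>: [landmarks...]
    """
    path = Path(path) if path is not None else default_config_path()
    cfg = yaml.safe_load(path.read_text())

    try:
        k = int(cfg["landmarks"])
        pairs = tuple(tuple(int(v) for v in p) for p in cfg["pairs"])
        midline = tuple(int(v) for v in cfg["midline"])
        scheme = PairingScheme(
            pairs=pairs,
            midline=midline,
            axis_reference=int(cfg["axis_reference"]),
            longitudinal_order=tuple(int(v) for v in cfg["longitudinal_order"]),
        )
    except KeyError as exc:
        raise ConfigError(f"{path.name}: missing key {exc}") from exc
    if scheme.n_landmarks != k:
        raise ConfigError(
            f"{path.name}: landmarks={k} but pairs/midline imply "
            f"{scheme.n_landmarks}"
        )
    for p in pairs:
        for v in p:
            if not 1 <= v <= k:
                raise ConfigError(f"{path.name}: landmark {v} out of range 1..{k}")

    partitions: list[ModulePartition] = []
    for name, modules in cfg.get("partitions", {}).items():
        assignment: dict[int, str] = {}
        for label, landmarks in modules.items():
            for lm in landmarks:
                lm = int(lm)
                if lm in assignment:
                    raise ConfigError(
                        f"{path.name}: partition {name!r} assigns landmark "
                        f"{lm} twice"
                    )
                if not 1 <= lm <= k:
                    raise ConfigError(
                        f"{path.name}: partition {name!r}: landmark {lm} "
                        f"out of range 1..{k}"
                    )
                assignment[lm] = str(label)
        if len(assignment) != k:
            missing = sorted(set(range(1, k + 1)) - set(assignment))
            raise ConfigError(
                f"{path.name}: partition {name!r} leaves landmarks "
                f"{missing} unassigned"
            )
        partitions.append(ModulePartition(name=name, assignment=assignment))
    return scheme, partitions
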
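"""Domain types and I/O for habitat x species interaction data.

The central object is the weighted interaction ("flux") matrix ``A`` with
habitats as rows and species as columns: ``A[i, j]`` is the number of
individuals of species ``j`` recorded in habitat ``i``.  Species carry a
residency class (resident or migrant) and an optional exclusion flag used
to re-run analyses without a hyper-abundant colonial species; habitats
carry an area in hectares.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Residency",
    "InteractionMatrix",
    "SpeciesInfo",
    "HabitatInfo",
    "CommunityDataset",
    "read_dataset",
    "write_dataset",
    "binarize",
    "subset_by_residency",
    "drop_excluded",
]


class Residency(str, Enum):
    """Residency class of a bird species."""

    RESIDENT = "resident"
    MIGRANT = "migrant"


def _check_unique(labels: Iterable[str], axis: str) -> tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {axis} label: {lab!r}")
        seen.add(lab)
    return labels


@dataclass(frozen=True)
class InteractionMatrix:
    """Habitats x species matrix of non-negative integer counts.

    Rows are habitats, columns are species.  Counts must be integral and
    non-negative; labels must be unique within each axis.  All-zero rows
    or columns are permitted on the type itself (removal experiments and
    residency subsets produce them); use :meth:`validated` to strip them
    with a warning, as done when reading data from disk.
    """

    habitat_labels: tuple[str, ...]
    species_labels: tuple[str, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integral")
            counts = np.round(counts).astype(np.int64)
        else:
            counts = counts.astype(np.int64, copy=True)
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be non-negative")
        habitat_labels = _check_unique(self.habitat_labels, "habitat")
        species_labels = _check_unique(self.species_labels, "species")
        if counts.shape != (len(habitat_labels), len(species_labels)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(habitat_labels)} habitats x {len(species_labels)} species"
            )
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "habitat_labels", habitat_labels)
        object.__setattr__(self, "species_labels", species_labels)

    # -- constructors -------------------------------------------------

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "InteractionMatrix":
        """Build from a DataFrame with habitat index and species columns."""
        return cls(
            habitat_labels=tuple(str(i) for i in frame.index),
            species_labels=tuple(str(c) for c in frame.columns),
            counts=frame.to_numpy(),
        )

    def validated(self) -> "InteractionMatrix":
        """Return a copy with all-zero rows and columns stripped.

        Emits a :class:`UserWarning` naming each dropped label; zero
        margins would otherwise break dependence denominators downstream.
        """
        out = self
        zero_rows = [
            lab for lab, s in zip(out.habitat_labels, out.row_sums()) if s == 0
        ]
        zero_cols = [
            lab for lab, s in zip(out.species_labels, out.col_sums()) if s == 0
        ]
        if zero_rows:
            warnings.warn(
                f"dropping habitat(s) with no observations: {zero_rows}",
                stacklevel=2,
            )
            out = out.drop_habitats(zero_rows)
        if zero_cols:
            warnings.warn(
                f"dropping species with no observations: {zero_cols}",
                stacklevel=2,
            )
            out = out.drop_species(zero_cols)
        return out

    # -- views and summaries ------------------------------------------

    @property
    def n_habitats(self) -> int:
        return len(self.habitat_labels)

    @property
    def n_species(self) -> int:
        return len(self.species_labels)

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def total(self) -> int:
        return int(self.counts.sum())

    def link_count(self) -> int:
        """Number of realized habitat-species links (positive cells)."""
        return int(np.count_nonzero(self.counts))

    def habitat_index(self, habitat: str) -> int:
        try:
            return self.habitat_labels.index(habitat)
        except ValueError:
            raise KeyError(f"unknown habitat: {habitat!r}") from None

    def row(self, habitat: str) -> np.ndarray:
        return self.counts[self.habitat_index(habitat)]

    def degrees(self) -> np.ndarray:
        """Per-habitat species counts (row degrees of the binary matrix)."""
        return np.count_nonzero(self.counts, axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.copy(),
            index=list(self.habitat_labels),
            columns=list(self.species_labels),
        )

    # -- derived matrices ---------------------------------------------

    def select_species(self, labels: Iterable[str]) -> "InteractionMatrix":
        labels = list(labels)
        idx = [self.species_labels.index(x) for x in labels]
        return InteractionMatrix(
            self.habitat_labels, tuple(labels), self.counts[:, idx]
        )

    def drop_species(self, labels: Iterable[str]) -> "InteractionMatrix":
        drop = set(labels)
        keep = [x for x in self.species_labels if x not in drop]
        return self.select_species(keep)

    def drop_habitats(self, labels: Iterable[str]) -> "InteractionMatrix":
        drop = set(labels)
        for lab in drop:
            self.habitat_index(lab)  # raise on unknown
        keep = [i for i, x in enumerate(self.habitat_labels) if x not in drop]
        return InteractionMatrix(
            tuple(self.habitat_labels[i] for i in keep),
            self.species_labels,
            self.counts[keep],
        )

    def with_counts(self, counts: np.ndarray) -> "InteractionMatrix":
        return InteractionMatrix(self.habitat_labels, self.species_labels, counts)


def binarize(matrix: InteractionMatrix) -> InteractionMatrix:
    """Presence-absence version of the matrix: positive cells become 1."""
    return matrix.with_counts((matrix.counts > 0).astype(np.int64))


@dataclass(frozen=True)
class SpeciesInfo:
    species_label: str
    residency: Residency
    exclude_flag: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "residency", Residency(self.residency))


@dataclass(frozen=True)
class HabitatInfo:
    habitat_label: str
    area_ha: float

    def __post_init__(self) -> None:
        if not self.area_ha > 0:
            raise ValueError(
                f"habitat {self.habitat_label!r}: area_ha must be positive"
            )


@dataclass(frozen=True)
class CommunityDataset:
    """Validated bundle of the interaction matrix and its metadata.

    Metadata keys cover the matrix labels exactly.  ``empty_habitats``
    records habitats whose row became all-zero through subsetting (they
    are kept in the matrix so similarity trees retain all leaves).
    """

    matrix: InteractionMatrix
    species_meta: Mapping[str, SpeciesInfo]
    habitat_meta: Mapping[str, HabitatInfo]
    empty_habitats: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        mat_sp = set(self.matrix.species_labels)
        meta_sp = set(self.species_meta)
        if mat_sp != meta_sp:
            missing = sorted(mat_sp - meta_sp)
            extra = sorted(meta_sp - mat_sp)
            raise ValueError(
                f"species metadata mismatch: missing {missing}, extra {extra}"
            )
        mat_h = set(self.matrix.habitat_labels)
        meta_h = set(self.habitat_meta)
        if mat_h != meta_h:
            missing = sorted(mat_h - meta_h)
            extra = sorted(meta_h - mat_h)
            raise ValueError(
                f"habitat metadata mismatch: missing {missing}, extra {extra}"
            )

    @property
    def is_empty(self) -> bool:
        """True when no species remain (degenerate subset result)."""
        return self.matrix.n_species == 0

    def residency_of(self, species: str) -> Residency:
        return self.species_meta[species].residency

    def species_by_residency(self, residency: Residency | str) -> list[str]:
        residency = Residency(residency)
        return [
            s
            for s in self.matrix.species_labels
            if self.species_meta[s].residency is residency
        ]

    def areas(self) -> dict[str, float]:
        return {
            h: self.habitat_meta[h].area_ha for h in self.matrix.habitat_labels
        }

    def summary(self) -> dict:
        m = self.matrix
        return {
            "n_habitats": m.n_habitats,
            "n_species": m.n_species,
            "n_links": m.link_count(),
            "total_individuals": m.total(),
            "n_resident": len(self.species_by_residency(Residency.RESIDENT)),
            "n_migrant": len(self.species_by_residency(Residency.MIGRANT)),
            "empty_habitats": list(self.empty_habitats),
        }


# ---------------------------------------------------------------------------
# readers / writers


def _read_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in {"1", "true", "yes"}
    return bool(x)


def read_dataset(
    matrix_path: str | Path,
    species_meta_path: str | Path,
    habitat_meta_path: str | Path,
) -> CommunityDataset:
    """Read and validate a community dataset from its three input files.

    ``matrix_path``: CSV, first column habitat labels, header row species
    labels, integer counts.  ``species_meta_path``: TSV with columns
    ``species_label``, ``residency``, ``exclude_flag``.
    ``habitat_meta_path``: TSV with columns ``habitat_label``, ``area_ha``.

    All-zero matrix rows/columns are stripped with a warning; any label
    present in the matrix but absent from metadata (or vice versa) raises.
    """
    frame = pd.read_csv(matrix_path, index_col=0)
    matrix = InteractionMatrix.from_frame(frame).validated()

    sp = pd.read_csv(species_meta_path, sep="\t", dtype=str)
    required = {"species_label", "residency"}
    if not required <= set(sp.columns):
        raise ValueError(
            f"species metadata must have columns {sorted(required)}"
        )
    species_meta = {}
    for _, rec in sp.iterrows():
        label = str(rec["species_label"])
        if label in species_meta:
            raise ValueError(f"duplicate species metadata record: {label!r}")
        species_meta[label] = SpeciesInfo(
            species_label=label,
            residency=Residency(rec["residency"]),
            exclude_flag=_read_bool(rec.get("exclude_flag", False)),
        )

    hb = pd.read_csv(habitat_meta_path, sep="\t")
    if not {"habitat_label", "area_ha"} <= set(hb.columns):
        raise ValueError(
            "habitat metadata must have columns habitat_label, area_ha"
        )
    habitat_meta = {}
    for _, rec in hb.iterrows():
        label = str(rec["habitat_label"])
        if label in habitat_meta:
            raise ValueError(f"duplicate habitat metadata record: {label!r}")
        habitat_meta[label] = HabitatInfo(label, float(rec["area_ha"]))

    # restrict metadata to labels that survived validation, but a matrix
    # label without metadata is an error
    for s in matrix.species_labels:
        if s not in species_meta:
            raise ValueError(f"species {s!r} missing from metadata")
    for h in matrix.habitat_labels:
        if h not in habitat_meta:
            raise ValueError(f"habitat {h!r} missing from metadata")
    species_meta = {s: species_meta[s] for s in matrix.species_labels}
    habitat_meta = {h: habitat_meta[h] for h in matrix.habitat_labels}
    return CommunityDataset(matrix, species_meta, habitat_meta)


def write_dataset(dataset: CommunityDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write matrix.csv, species.tsv and habitats.tsv under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.csv",
        "species": out_dir / "species.tsv",
        "habitats": out_dir / "habitats.tsv",
    }
    dataset.matrix.to_frame().to_csv(paths["matrix"])
    pd.DataFrame(
        {
            "species_label": list(dataset.matrix.species_labels),
            "residency": [
                dataset.species_meta[s].residency.value
                for s in dataset.matrix.species_labels
            ],
            "exclude_flag": [
                dataset.species_meta[s].exclude_flag
                for s in dataset.matrix.species_labels
            ],
        }
    ).to_csv(paths["species"], sep="\t", index=False)
    pd.DataFrame(
        {
            "habitat_label": list(dataset.matrix.habitat_labels),
            "area_ha": [
                dataset.habitat_meta[h].area_ha
                for h in dataset.matrix.habitat_labels
            ],
        }
    ).to_csv(paths["habitats"], sep="\t", index=False)
    return paths


def write_summary_json(dataset: CommunityDataset, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataset.summary(), indent=2))


# ---------------------------------------------------------------------------
# subsetting


def subset_by_residency(
    dataset: CommunityDataset, residency: Residency | str
) -> CommunityDataset:
    """Restrict to species of one residency class.

    Habitat rows are retained even when they become all-zero, so
    similarity trees over residency subsets keep every habitat leaf;
    such habitats are listed in ``empty_habitats`` on the result.
    """
    residency = Residency(residency)
    keep = dataset.species_by_residency(residency)
    matrix = dataset.matrix.select_species(keep)
    empty = tuple(
        lab
        for lab, s in zip(matrix.habitat_labels, matrix.row_sums())
        if s == 0
    )
    return CommunityDataset(
        matrix,
        {s: dataset.species_meta[s] for s in keep},
        dict(dataset.habitat_meta),
        empty_habitats=empty,
    )


def drop_excluded(dataset: CommunityDataset) -> CommunityDataset:
    """Remove species marked with ``exclude_flag`` (the colonial-species
    analog), producing the "-excluded" variant of the dataset."""
    flagged = [
        s
        for s in dataset.matrix.species_labels
        if dataset.species_meta[s].exclude_flag
    ]
    if not flagged:
        return dataset
    matrix = dataset.matrix.drop_species(flagged)
    empty = tuple(
        lab
        for lab, s in zip(matrix.habitat_labels, matrix.row_sums())
        if s == 0
    )
    return CommunityDataset(
        matrix,
        {s: dataset.species_meta[s] for s in matrix.species_labels},
        dict(dataset.habitat_meta),
        empty_habitats=empty,
    )
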
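"""Marker coding and genotype distance matrices.

Biallelic marker calls are coded into a covariate matrix ``Z`` with one row
per individual and one column per marker, entries in {-1, 0, 1}: homozygotes
of the two alleles map to +1 and -1, heterozygotes (either order) to 0.
Euclidean distances between the rows of ``Z`` feed the geostatistical
covariance kernels, analogous to spatial distance in geostatistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "DEFAULT_CODING",
    "GenotypeMatrix",
    "DistanceMatrix",
    "CodingError",
    "code_markers",
    "distance_matrix",
    "cross_distance",
    "read_genotypes",
]

#: allele-pair label -> integer code; both heterozygote orders collapse to 0
DEFAULT_CODING: dict[str, int] = {"A1A1": 1, "A2A2": -1, "A1A2": 0, "A2A1": 0}


class CodingError(ValueError):
    """Raised when a genotype call cannot be coded."""


@dataclass(frozen=True)
class GenotypeMatrix:
    """Coded marker covariates: individuals x markers, entries in {-1, 0, 1}."""

    Z: np.ndarray
    individual_ids: tuple[str, ...]
    marker_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        Z = np.asarray(self.Z, dtype=float)
        if Z.ndim != 2:
            raise ValueError("Z must be 2-dimensional")
        if Z.shape != (len(self.individual_ids), len(self.marker_ids)):
            raise ValueError(
                f"Z shape {Z.shape} does not match id lists "
                f"({len(self.individual_ids)} x {len(self.marker_ids)})"
            )
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("individual ids are not unique")
        object.__setattr__(self, "Z", Z)

    @property
    def n_individuals(self) -> int:
        return self.Z.shape[0]

    @property
    def n_markers(self) -> int:
        return self.Z.shape[1]

    def subset(self, ids) -> "GenotypeMatrix":
        """Rows for ``ids``, in that order; unknown ids raise KeyError."""
        index = {g: i for i, g in enumerate(self.individual_ids)}
        try:
            rows = [index[i] for i in ids]
        except KeyError as exc:
            raise KeyError(f"individual {exc.args[0]!r} has no genotype") from None
        return GenotypeMatrix(self.Z[rows], tuple(ids), self.marker_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.Z,
            index=pd.Index(self.individual_ids, name="individual"),
            columns=list(self.marker_ids),
        )


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise Euclidean distances between genotype rows."""

    D: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if D.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        object.__setattr__(self, "D", D)


def code_markers(
    table: pd.DataFrame,
    coding_map: dict | None = None,
    *,
    impute_missing: bool = False,
) -> GenotypeMatrix:
    """Code a genotype call table into the covariate matrix ``Z``.

    Parameters
    ----------
    table
        One row per individual (index = individual id), one column per
        marker.  Cells are allele-pair labels (e.g. ``"A1A2"``) or
        pre-coded integers in {-1, 0, 1}.  NaN marks a missing call.
    coding_map
        Label -> code mapping; defaults to :data:`DEFAULT_CODING`.
        Integer cells already in {-1, 0, 1} pass through unchanged.
    impute_missing
        Off by default (missing calls are a hard error).  When on, a
        missing call is replaced by the mean code of its marker column.
    """
    coding = dict(DEFAULT_CODING if coding_map is None else coding_map)
    ids = tuple(str(i) for i in table.index)
    markers = tuple(str(m) for m in table.columns)
    Z = np.empty((len(ids), len(markers)), dtype=float)
    missing: list[tuple[int, int]] = []
    values = table.to_numpy(dtype=object)
    for i in range(len(ids)):
        for k in range(len(markers)):
            cell = values[i, k]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                if not impute_missing:
                    raise CodingError(
                        f"missing call for individual {ids[i]!r}, marker "
                        f"{markers[k]!r} (imputation is off)"
                    )
                missing.append((i, k))
                Z[i, k] = np.nan
                continue
            if isinstance(cell, (int, np.integer)) or (
                isinstance(cell, float) and float(cell).is_integer()
            ):
                code = int(cell)
                if code not in (-1, 0, 1):
                    raise CodingError(
                        f"integer code {code} for individual {ids[i]!r}, marker "
                        f"{markers[k]!r} is not in {{-1, 0, 1}}"
                    )
                Z[i, k] = code
                continue
            label = str(cell)
            if label not in coding:
                raise CodingError(
                    f"unknown call {label!r} for individual {ids[i]!r}, "
                    f"marker {markers[k]!r}"
                )
            Z[i, k] = coding[label]
    if missing:
        col_means = np.nanmean(Z, axis=0)
        for i, k in missing:
            Z[i, k] = col_means[k] if np.isfinite(col_means[k]) else 0.0
    return GenotypeMatrix(Z, ids, markers)


def distance_matrix(genotypes: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise Euclidean distances ``d_ii' = ||z_i - z_i'||`` between rows of Z."""
    Z = genotypes.Z
    if not np.all(np.isfinite(Z)):
        raise ValueError("genotype matrix contains non-finite entries")
    D = squareform(pdist(Z, metric="euclidean"))
    return DistanceMatrix(D, tuple(genotypes.individual_ids))


def cross_distance(a: GenotypeMatrix, b: GenotypeMatrix) -> np.ndarray:
    """Rectangular distance block ``||z_i^a - z_j^b||`` (train/test plumbing)."""
    if a.marker_ids != b.marker_ids:
        raise ValueError("marker sets (or their order) differ between the two matrices")
    if not (np.all(np.isfinite(a.Z)) and np.all(np.isfinite(b.Z))):
        raise ValueError("genotype matrix contains non-finite entries")
    return cdist(a.Z, b.Z, metric="euclidean")


def read_genotypes(path, *, sep: str = ",", coding_map: dict | None = None,
                   impute_missing: bool = False) -> GenotypeMatrix:
    """Read a delimited genotype file: header of marker ids, first column id."""
    table = pd.read_csv(path, sep=sep, index_col=0, dtype=object)
    # numeric dialect: every cell parses as an integer code
    try:
        numeric = table.astype(float)
    except (TypeError, ValueError):
        numeric = None
    if numeric is not None:
        return code_markers(numeric, coding_map, impute_missing=impute_missing)
    return code_markers(table, coding_map, impute_missing=impute_missing)
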
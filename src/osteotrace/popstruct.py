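"""Population structure from haplogroup-frequency matrices.

Reference populations are rows of a population x haplogroup frequency
matrix; the study cohort, pooled as a single population, is appended as an
active row.  Principal component analysis is classical covariance PCA on
the column-mean-centred, unscaled frequencies (frequencies already share a
scale; per-column standardisation would inflate rare-haplogroup noise),
computed by singular value decomposition.  Sign convention: within each
component the largest-magnitude loading is made positive, so outputs are
reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ROW_SUM_TOLERANCE = 1e-9


class FrequencyValidationError(ValueError):
    """A frequency table row violates [0,1] bounds or sums above 1."""


@dataclass
class FrequencyTable:
    """Population x haplogroup fractions; row sums may be < 1 (unlisted haplogroups)."""

    frame: pd.DataFrame  # index = populations, columns = haplogroups

    def __post_init__(self) -> None:
        values = self.frame.to_numpy(dtype=float)
        if np.any(values < -ROW_SUM_TOLERANCE) or np.any(values > 1 + ROW_SUM_TOLERANCE):
            bad = self.frame.index[
                ((values < -ROW_SUM_TOLERANCE) | (values > 1 + ROW_SUM_TOLERANCE)).any(axis=1)
            ]
            raise FrequencyValidationError(
                f"frequencies outside [0,1] in rows: {list(bad)}"
            )
        sums = values.sum(axis=1)
        if np.any(sums > 1 + ROW_SUM_TOLERANCE):
            bad = self.frame.index[sums > 1 + ROW_SUM_TOLERANCE]
            raise FrequencyValidationError(f"row sums exceed 1 in rows: {list(bad)}")

    @property
    def populations(self) -> list[str]:
        return list(self.frame.index)

    @property
    def haplogroups(self) -> list[str]:
        return list(self.frame.columns)


@dataclass
class PCAResult:
    coordinates: pd.DataFrame      # populations x PC1..PCk
    eigenvalues: np.ndarray        # non-increasing
    loadings: pd.DataFrame         # haplogroups x PC1..PCk, orthonormal columns
    explained_fraction: np.ndarray


def build_frequency_matrix(
    reference: pd.DataFrame | FrequencyTable,
    cohort_frequencies: dict[str, float],
    cohort_id: str = "cohort",
) -> FrequencyTable:
    """Append the cohort as one population row; union of haplogroup columns.

    Haplogroups absent from either side are zero-filled; columns are sorted
    for deterministic order.
    """
    ref_frame = reference.frame if isinstance(reference, FrequencyTable) else reference
    cohort_row = pd.DataFrame(
        [cohort_frequencies], index=pd.Index([cohort_id], name=ref_frame.index.name)
    )
    merged = pd.concat([ref_frame, cohort_row]).fillna(0.0)
    merged = merged[sorted(merged.columns)]
    return FrequencyTable(merged)


def pca_frequencies(table: FrequencyTable, n_components: int = 2) -> PCAResult:
    """Covariance PCA of the centred frequency matrix via SVD.

    Eigenvalues are the per-component variances (divisor n-1); a constant
    matrix yields all-zero eigenvalues and coordinates, not an error.
    """
    X = table.frame.to_numpy(dtype=float)
    n_rows, n_cols = X.shape
    if n_rows < 2:
        raise ValueError("PCA requires at least 2 populations")
    max_components = min(n_rows - 1, n_cols)
    if n_components > max_components:
        raise ValueError(
            f"n_components={n_components} exceeds min(rows-1, columns)={max_components}"
        )
    centred = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    eigenvalues_all = s**2 / (n_rows - 1)
    total_variance = centred.var(axis=0, ddof=1).sum()

    loadings = vt[:n_components].T.copy()          # columns orthonormal
    coordinates = centred @ loadings
    # deterministic signs: largest-|loading| entry positive per component
    for j in range(n_components):
        pivot = np.argmax(np.abs(loadings[:, j]))
        if loadings[pivot, j] < 0:
            loadings[:, j] *= -1
            coordinates[:, j] *= -1

    pcs = [f"PC{i + 1}" for i in range(n_components)]
    explained = (
        eigenvalues_all[:n_components] / total_variance
        if total_variance > 0
        else np.zeros(n_components)
    )
    return PCAResult(
        coordinates=pd.DataFrame(coordinates, index=table.frame.index, columns=pcs),
        eigenvalues=eigenvalues_all[:n_components],
        loadings=pd.DataFrame(loadings, index=table.frame.columns, columns=pcs),
        explained_fraction=explained,
    )


def nearest_populations(
    result: PCAResult, focal: str, n_components: int = 2
) -> pd.Series:
    """Euclidean distance of every other population to ``focal`` in PC space,
    sorted ascending."""
    coords = result.coordinates.iloc[:, :n_components]
    deltas = coords - coords.loc[focal]
    distances = np.sqrt((deltas**2).sum(axis=1))
    return distances.drop(focal).sort_values(kind="stable")


# ---------------------------------------------------------------------------
# I/O


def read_frequency_csv(path: str) -> FrequencyTable:
    """Long-format CSV: population,haplogroup,frequency."""
    df = pd.read_csv(path)
    wide = (
        df.pivot_table(
            index="population", columns="haplogroup", values="frequency",
            aggfunc="sum", fill_value=0.0,
        )
        .sort_index(axis=1)
    )
    wide.index.name = "population"
    wide.columns.name = None
    return FrequencyTable(wide)


def write_frequency_csv(table: FrequencyTable, path: str) -> None:
    long = (
        table.frame.stack()
        .rename("frequency")
        .rename_axis(["population", "haplogroup"])
        .reset_index()
    )
    long = long[long["frequency"] > 0]
    long.to_csv(path, index=False)


def write_pca_csv(result: PCAResult, path: str) -> None:
    out = result.coordinates.copy()
    out.index.name = "population"
    out.to_csv(path)
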
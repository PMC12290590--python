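"""Reading, validating and writing cohorts of structural connectomes.

A cohort is a stack of per-subject symmetric, zero-diagonal, nonnegative
count matrices (e.g. streamline counts on a 68-region cortical parcellation),
together with per-subject nuisance covariates (e.g. RMS head motion in mm),
optional trait scores, node labels and subject ids.  Matrices live in plain
delimited text files, one per subject; metadata in a single CSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConnectomeCohort",
    "GroupAssignment",
    "load_cohort",
    "save_cohort",
    "assign_motion_groups",
]

#: maximum tolerated max|A - A^T| on load; undirected graphs are assumed
SYMMETRY_TOL = 1e-8


@dataclass
class ConnectomeCohort:
    """n subjects' adjacency matrices plus aligned metadata.

    adjacency : (n, V, V) nonnegative, symmetric, zero-diagonal
    nuisance  : (n, C) real; C = 0 means no nuisance channel (GATE mode)
    trait     : (n,) real, NaN marks a missing score
    """

    adjacency: np.ndarray
    nuisance: np.ndarray
    trait: np.ndarray
    node_labels: list[str] = field(default_factory=list)
    subject_ids: list[str] = field(default_factory=list)
    nuisance_units: str = "mm"

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        if self.adjacency.ndim != 3 or self.adjacency.shape[1] != self.adjacency.shape[2]:
            raise ValueError("adjacency must be (n, V, V)")
        n, V = self.adjacency.shape[:2]
        self.nuisance = np.asarray(self.nuisance, dtype=float).reshape(n, -1)
        if self.nuisance.shape[1] == 0:
            self.nuisance = self.nuisance.reshape(n, 0)
        self.trait = np.asarray(self.trait, dtype=float).reshape(-1)
        if self.trait.shape[0] != n:
            raise ValueError("trait length does not match number of subjects")
        if not self.node_labels:
            self.node_labels = [f"ROI_{i + 1}" for i in range(V)]
        if len(self.node_labels) != V:
            raise ValueError("node_labels length does not match V")
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i + 1:04d}" for i in range(n)]
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match n")
        self.validate()

    # -- basic facts -------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[1]

    @property
    def n_nuisance(self) -> int:
        return self.nuisance.shape[1]

    @property
    def trait_observed(self) -> np.ndarray:
        """Boolean mask of subjects with a non-missing trait score."""
        return ~np.isnan(self.trait)

    def validate(self) -> None:
        A = self.adjacency
        if not np.all(np.isfinite(A)):
            raise ValueError("adjacency contains non-finite entries")
        if np.any(A < 0):
            raise ValueError("adjacency contains negative entries")
        asym = np.max(np.abs(A - np.swapaxes(A, 1, 2))) if A.size else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(f"adjacency asymmetry {asym:.3g} exceeds tolerance")
        diag = np.abs(A[:, np.arange(A.shape[1]), np.arange(A.shape[1])])
        if A.size and diag.max() > 0:
            raise ValueError("adjacency has nonzero diagonal (self-connections)")

    def subset(self, idx) -> "ConnectomeCohort":
        idx = np.asarray(idx)
        return ConnectomeCohort(
            adjacency=self.adjacency[idx],
            nuisance=self.nuisance[idx],
            trait=self.trait[idx],
            node_labels=list(self.node_labels),
            subject_ids=[self.subject_ids[i] for i in idx],
            nuisance_units=self.nuisance_units,
        )


@dataclass
class GroupAssignment:
    """Per-subject membership in the small/large extreme groups."""

    labels: list[str]
    low_percentile: float
    high_percentile: float

    @property
    def small(self) -> np.ndarray:
        return np.array([lab == "small" for lab in self.labels])

    @property
    def large(self) -> np.ndarray:
        return np.array([lab == "large" for lab in self.labels])


def _read_matrix(path: os.PathLike) -> np.ndarray:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delim = "," if "," in first else None
    try:
        M = np.loadtxt(path, delimiter=delim, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: could not parse as a numeric grid ({exc})")
    if M.shape[0] != M.shape[1]:
        raise ValueError(f"{path}: matrix is {M.shape[0]}x{M.shape[1]}, expected square")
    return M


def load_cohort(
    matrix_paths: list[os.PathLike],
    metadata_path: os.PathLike,
    nuisance_cols: list[str] | None = None,
    trait_col: str | None = None,
    node_labels: list[str] | None = None,
    symmetry_tol: float = SYMMETRY_TOL,
) -> ConnectomeCohort:
    """Load one matrix file per subject plus a metadata CSV.

    Matrix files are matched to metadata rows by file stem == ``subject_id``.
    Small asymmetries (max|A - A^T| <= ``symmetry_tol``) are repaired by
    averaging (A + A^T)/2; anything larger is an error.  Nuisance columns
    default to every column whose name starts with ``nuisance``; the trait
    column defaults to ``trait`` when present.
    """
    meta = pd.read_csv(metadata_path, dtype={"subject_id": str},
                       float_precision="round_trip")
    if "subject_id" not in meta.columns:
        raise ValueError("metadata must contain a subject_id column")
    if nuisance_cols is None:
        nuisance_cols = [c for c in meta.columns if c.startswith("nuisance")]
    if trait_col is None and "trait" in meta.columns:
        trait_col = "trait"

    by_stem = {Path(p).stem: Path(p) for p in matrix_paths}
    ids = list(meta["subject_id"])
    missing = [s for s in ids if s not in by_stem]
    extra = [s for s in by_stem if s not in set(ids)]
    if missing or extra:
        raise ValueError(
            f"subject_id mismatch between matrices and metadata "
            f"(missing files for {missing[:5]}, unmatched files {extra[:5]})"
        )

    mats = []
    V = None
    for sid in ids:
        M = _read_matrix(by_stem[sid])
        if V is None:
            V = M.shape[0]
        elif M.shape[0] != V:
            raise ValueError(
                f"{by_stem[sid]}: dimension {M.shape[0]} differs from first subject ({V})"
            )
        if np.any(M < 0):
            raise ValueError(f"{by_stem[sid]}: negative entries")
        asym = np.max(np.abs(M - M.T))
        if asym > symmetry_tol:
            raise ValueError(
                f"{by_stem[sid]}: asymmetry {asym:.3g} exceeds tolerance {symmetry_tol:.3g}"
            )
        M = (M + M.T) / 2.0
        np.fill_diagonal(M, 0.0)
        mats.append(M)

    nuis = meta[nuisance_cols].to_numpy(dtype=float) if nuisance_cols else np.zeros((len(ids), 0))
    trait = meta[trait_col].to_numpy(dtype=float) if trait_col else np.full(len(ids), np.nan)
    return ConnectomeCohort(
        adjacency=np.stack(mats) if mats else np.zeros((0, 0, 0)),
        nuisance=nuis,
        trait=trait,
        node_labels=node_labels or [],
        subject_ids=ids,
    )


def save_cohort(cohort: ConnectomeCohort, out_dir: os.PathLike) -> list[Path]:
    """Write one delimited matrix file per subject plus ``metadata.csv``.

    File naming is deterministic (``<subject_id>.txt``); integer counts
    round-trip bit-exactly through :func:`load_cohort`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for i, sid in enumerate(cohort.subject_ids):
        p = out / f"{sid}.txt"
        np.savetxt(p, cohort.adjacency[i], fmt="%.10g", delimiter="\t")
        written.append(p)
    meta = pd.DataFrame({"subject_id": cohort.subject_ids})
    for j in range(cohort.n_nuisance):
        meta[f"nuisance_{j + 1}"] = cohort.nuisance[:, j]
    meta["trait"] = cohort.trait
    mpath = out / "metadata.csv"
    # %.17g round-trips IEEE doubles exactly through text
    meta.to_csv(mpath, index=False, float_format="%.17g")
    written.append(mpath)
    return written


def assign_motion_groups(
    values, low_pct: float = 5.0, high_pct: float = 95.0
) -> GroupAssignment:
    """Assign subjects to small/large extreme groups of a scalar covariate.

    The bottom ``low_pct`` percent of subjects by value form the *small*
    group and the top ``100 - high_pct`` percent the *large* group, using the
    nearest-rank convention: group size = ceil(p/100 * n).  Ties in value are
    broken by subject order (stable sort), so group sizes are exact.
    """
    values = np.asarray(values, dtype=float).reshape(-1)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects to form groups")
    if not (0 < low_pct < high_pct < 100):
        raise ValueError("require 0 < low_pct < high_pct < 100")
    if np.all(values == values[0]):
        raise ValueError("all covariate values identical; percentile groups undefined")
    n_small = int(np.ceil(low_pct / 100.0 * n))
    n_large = int(np.ceil((100.0 - high_pct) / 100.0 * n))
    order = np.argsort(values, kind="stable")
    labels = ["neither"] * n
    for i in order[:n_small]:
        labels[i] = "small"
    for i in order[n - n_large:]:
        labels[i] = "large"
    return GroupAssignment(labels=labels, low_percentile=low_pct, high_percentile=high_pct)
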
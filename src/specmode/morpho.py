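"""Morphological divergence: species means, Mahalanobis D2, canonical axes.

Four specimen measurements (capitulum length/width, leaf length/width, mm)
serve as a proxy for adaptive differentiation.  Divergence between species
is the Mahalanobis distance between species mean vectors in the metric of
the pooled within-species covariance: measurements are implicitly
transformed into standardized, uncorrelated variables, so distances account
for both scale differences and trait correlations.  The same pooled metric
underlies the discriminant (canonical variates) projection used to display
group separation on two axes.

Distances are reported squared (D2), with the square root D emitted as a
secondary column in the CSV writer.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg

logger = logging.getLogger(__name__)

TRAIT_NAMES = ("cap_len_mm", "cap_wid_mm", "leaf_len_mm", "leaf_wid_mm")

#: pooled covariance condition number beyond which we refuse to invert
SINGULARITY_CONDITION_LIMIT = 1e12


class SingularCovarianceError(np.linalg.LinAlgError):
    """Pooled within-group covariance is (near-)singular.

    Remove a redundant trait or regularize; no silent pseudo-inverse is
    applied.
    """


@dataclass(frozen=True)
class SpecimenRecord:
    """One measured herbarium specimen."""

    specimen_id: str
    species_id: str
    cap_len_mm: float
    cap_wid_mm: float
    leaf_len_mm: float
    leaf_wid_mm: float

    def values(self) -> np.ndarray:
        return np.array(
            [self.cap_len_mm, self.cap_wid_mm, self.leaf_len_mm, self.leaf_wid_mm]
        )

    def __post_init__(self) -> None:
        v = self.values()
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValueError(
                f"specimen {self.specimen_id!r}: all four measurements must be "
                f"finite and positive, got {v.tolist()}"
            )


@dataclass
class TraitSummary:
    """Per-species mean vector and within-species covariance (n >= 2)."""

    species_id: str
    mean_vector: np.ndarray
    n_specimens: int
    within_covariance: np.ndarray | None  # None when n < 2


@dataclass
class MahalanobisMatrix:
    species_ids: list[str]
    values: np.ndarray  # squared distances

    def get(self, a: str, b: str) -> float:
        return float(
            self.values[self.species_ids.index(a), self.species_ids.index(b)]
        )

    def to_csv(self, path: str | Path) -> None:
        """Square CSV of D2 followed by a long-format D2/D section."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["species"] + self.species_ids)
            for sp, row in zip(self.species_ids, self.values):
                w.writerow([sp] + [f"{v:.10g}" for v in row])
            w.writerow([])
            w.writerow(["species_a", "species_b", "d2", "d"])
            for i, a in enumerate(self.species_ids):
                for j in range(i + 1, len(self.species_ids)):
                    d2 = self.values[i, j]
                    w.writerow(
                        [a, self.species_ids[j], f"{d2:.10g}", f"{np.sqrt(d2):.10g}"]
                    )


@dataclass
class DfaProjection:
    """Canonical-variates projection maximizing between/within scatter."""

    species_ids: list[str]
    eigenvalues: np.ndarray  # all k-1 (<= n traits) canonical roots, descending
    axes: np.ndarray  # traits x axes, full canonical basis
    species_scores: np.ndarray  # species x axes
    specimen_scores: np.ndarray  # specimens x axes
    specimen_species: list[str]


# ---------------------------------------------------------------------------


def read_specimens(path: str | Path) -> list[SpecimenRecord]:
    """Read specimen measurements CSV; invalid rows are rejected and logged.

    Required columns: specimen, species and the four trait columns
    (cap_len_mm, cap_wid_mm, leaf_len_mm, leaf_wid_mm).  Extra columns are
    ignored with a log message.  Rows with missing or non-positive
    measurements are dropped, each reported at WARNING level.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"specimen", "species", *TRAIT_NAMES}
        if reader.fieldnames is None or required - set(reader.fieldnames):
            missing = sorted(required - set(reader.fieldnames or []))
            raise ValueError(f"{path}: missing required columns {missing}")
        extra = set(reader.fieldnames) - required
        if extra:
            logger.info("%s: ignoring extra columns %s", path, sorted(extra))
        out: list[SpecimenRecord] = []
        n_rejected = 0
        for i, row in enumerate(reader, start=2):
            try:
                out.append(
                    SpecimenRecord(
                        specimen_id=row["specimen"].strip(),
                        species_id=row["species"].strip(),
                        **{t: float(row[t]) for t in TRAIT_NAMES},
                    )
                )
            except (ValueError, TypeError) as exc:
                n_rejected += 1
                logger.warning("%s row %d rejected: %s", path, i, exc)
        if n_rejected:
            logger.warning("%s: rejected %d invalid rows", path, n_rejected)
    return out


def summarize_species(specimens: Sequence[SpecimenRecord]) -> list[TraitSummary]:
    """Species trait means and (n-1)-denominator covariances.

    Species observed once get a mean but no covariance (flagged by None);
    they still enter distance computations through their mean.
    """
    by_sp: dict[str, list[np.ndarray]] = {}
    for s in specimens:
        by_sp.setdefault(s.species_id, []).append(s.values())
    out = []
    for sp in sorted(by_sp):
        X = np.vstack(by_sp[sp])
        n = X.shape[0]
        cov = np.cov(X, rowvar=False, ddof=1) if n >= 2 else None
        out.append(TraitSummary(sp, X.mean(axis=0), n, cov))
    return out


def pooled_within_covariance(summaries: Sequence[TraitSummary]) -> np.ndarray:
    """Pooled within-species covariance: sum (n_i - 1) S_i / (N - k).

    Only species with n >= 2 contribute scatter; N and k count those
    species.  This is the scatter matrix a discriminant analysis pools
    across groups.
    """
    contrib = [s for s in summaries if s.within_covariance is not None]
    if len(contrib) < 2:
        raise ValueError("need >= 2 species with >= 2 specimens to pool covariance")
    p = contrib[0].mean_vector.size
    scatter = np.zeros((p, p))
    n_total = 0
    for s in contrib:
        scatter += (s.n_specimens - 1) * s.within_covariance
        n_total += s.n_specimens
    pooled = scatter / (n_total - len(contrib))
    return 0.5 * (pooled + pooled.T)


def _checked_inverse_factor(pooled: np.ndarray) -> np.ndarray:
    """Cholesky factor of pooled^-1 usable for whitening; error if singular."""
    cond = np.linalg.cond(pooled)
    if not np.isfinite(cond) or cond > SINGULARITY_CONDITION_LIMIT:
        raise SingularCovarianceError(
            f"pooled covariance is singular or near-singular "
            f"(condition number {cond:.3g}); remove a redundant/constant trait "
            f"or regularize before computing distances"
        )
    L = np.linalg.cholesky(pooled)
    return L


def mahalanobis_matrix(
    summaries: Sequence[TraitSummary], pooled: np.ndarray
) -> MahalanobisMatrix:
    """Pairwise squared Mahalanobis distances between species means.

    D2(i,j) = (mu_i - mu_j)^T pooled^-1 (mu_i - mu_j).
    """
    L = _checked_inverse_factor(pooled)
    ids = [s.species_id for s in summaries]
    means = np.vstack([s.mean_vector for s in summaries])
    # whiten: z = L^-1 mu, then D2 is squared Euclidean
    Z = scipy.linalg.solve_triangular(L, means.T, lower=True).T
    diff = Z[:, None, :] - Z[None, :, :]
    D2 = np.einsum("ijk,ijk->ij", diff, diff)
    D2 = 0.5 * (D2 + D2.T)
    np.fill_diagonal(D2, 0.0)
    return MahalanobisMatrix(ids, D2)


def dfa_project(
    specimens: Sequence[SpecimenRecord],
    summaries: Sequence[TraitSummary] | None = None,
    level: str = "specimen",
) -> DfaProjection:
    """Canonical variates (discriminant functions) of the trait data.

    Axes are eigenvectors of pooled^-1 B, where B is the between-group
    scatter of species means (weighted by n_i at ``level="specimen"``,
    unweighted at ``level="species"``), normalized so the within-group
    variance of scores is 1 on every axis.  Species centroids and specimen
    scores on the leading axes give the familiar DFA biplot; squared
    Euclidean distance between two centroids across the *full* canonical
    basis reproduces their Mahalanobis D2.
    """
    if level not in ("specimen", "species"):
        raise ValueError("level must be 'specimen' or 'species'")
    if summaries is None:
        summaries = summarize_species(specimens)
    pooled = pooled_within_covariance(summaries)
    _checked_inverse_factor(pooled)  # fail early on singularity
    ids = [s.species_id for s in summaries]
    means = np.vstack([s.mean_vector for s in summaries])
    ns = np.array([s.n_specimens for s in summaries], dtype=float)
    if level == "species":
        ns = np.ones_like(ns)
    grand = (ns[:, None] * means).sum(axis=0) / ns.sum()
    dev = means - grand
    B = (ns[:, None] * dev).T @ dev
    # generalized symmetric-definite eigenproblem B v = lambda W v with
    # eigenvectors normalized v^T W v = 1 (unit within-group score variance)
    eigvals, eigvecs = scipy.linalg.eigh(B, pooled)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    axes = eigvecs[:, order]
    species_scores = (means - grand) @ axes
    spec_X = np.vstack([s.values() for s in specimens])
    specimen_scores = (spec_X - grand) @ axes
    return DfaProjection(
        species_ids=ids,
        eigenvalues=eigvals,
        axes=axes,
        species_scores=species_scores,
        specimen_scores=specimen_scores,
        specimen_species=[s.species_id for s in specimens],
    )


# ---------------------------------------------------------------------------
# writers


def write_species_means(summaries: Sequence[TraitSummary], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["species", "n_specimens", *TRAIT_NAMES])
        for s in summaries:
            w.writerow(
                [s.species_id, s.n_specimens]
                + [f"{v:.6f}" for v in s.mean_vector]
            )


def write_dfa_scores(proj: DfaProjection, path: str | Path) -> None:
    """Specimen scores on the first two canonical axes plus centroids."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["kind", "label", "species", "axis1", "axis2"])
        for sp, score in zip(proj.species_ids, proj.species_scores):
            w.writerow(["centroid", sp, sp, f"{score[0]:.6f}", f"{score[1]:.6f}"])
        for i, (sp, score) in enumerate(
            zip(proj.specimen_species, proj.specimen_scores)
        ):
            w.writerow(["specimen", f"s{i}", sp, f"{score[0]:.6f}", f"{score[1]:.6f}"])
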
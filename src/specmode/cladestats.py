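"""Clade-level contrasts of pairwise overlap or divergence values.

Given a symmetric species-by-species matrix (range-overlap proportions or
Mahalanobis D2) and an assignment of species to two clades, the contrast
compares the within-clade pairwise values of the two clades with a
pooled-variance Student t-test (df = n1 + n2 - 2 pairwise values), and with
a randomization null in which clade labels are permuted across *species* —
not across pairs — so the non-independence of pairs sharing a species is
respected in the null.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.stats

DEFAULT_N_PERMUTATIONS = 9999


@dataclass
class CladeAssignment:
    """Mapping species -> clade label; each species carries exactly one."""

    mapping: dict[str, str]

    def species_in(self, label: str) -> list[str]:
        return sorted(sp for sp, lab in self.mapping.items() if lab == label)

    def labels(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    @classmethod
    def from_csv(cls, path: str | Path) -> "CladeAssignment":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or {"species", "clade"} - set(
                reader.fieldnames
            ):
                raise ValueError(f"{path}: need columns species,clade")
            mapping: dict[str, str] = {}
            for row in reader:
                sp = row["species"].strip()
                if sp in mapping:
                    raise ValueError(f"{path}: species {sp!r} assigned twice")
                mapping[sp] = row["clade"].strip()
        return cls(mapping)


@dataclass
class CladeComparisonResult:
    statistic_name: str
    group_values: tuple[list[float], list[float]]
    t: float
    df: int
    p_parametric: float
    p_permutation: float | None = None
    n_permutations: int = 0
    seed: int | None = None
    group_labels: tuple[str, str] = ("a", "b")
    extras: dict = field(default_factory=dict)

    def report(self) -> str:
        g1, g2 = self.group_values
        la, lb = self.group_labels
        lines = [
            f"Contrast of {self.statistic_name}: clade {la} vs clade {lb}",
            f"  clade {la}: {len(g1)} within-clade pairs, mean {np.mean(g1):.4f}",
            f"  clade {lb}: {len(g2)} within-clade pairs, mean {np.mean(g2):.4f}",
            f"  pooled t = {self.t:.4f}, df = {self.df}, "
            f"two-sided parametric P = {self.p_parametric:.4g}",
        ]
        if self.p_permutation is not None:
            lines.append(
                f"  species-label permutation P = {self.p_permutation:.4g} "
                f"({self.n_permutations} permutations, seed {self.seed})"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------


def _matrix_and_ids(M) -> tuple[np.ndarray, list[str]]:
    """Accept OverlapMatrix / MahalanobisMatrix / (ids, array) duck-typed."""
    return np.asarray(M.values, dtype=float), list(M.species_ids)


def within_clade_pairs(M, clades: CladeAssignment, label: str) -> list[float]:
    """Upper-triangle matrix values among the species carrying ``label``.

    Order is deterministic: species sorted alphabetically, pairs in
    itertools.combinations order.
    """
    values, ids = _matrix_and_ids(M)
    members = [sp for sp in clades.species_in(label) if sp in ids]
    missing = set(clades.species_in(label)) - set(ids)
    if missing:
        raise ValueError(f"clade {label!r} species missing from matrix: {sorted(missing)}")
    if len(members) < 2:
        raise ValueError(f"clade {label!r} has fewer than 2 species in the matrix")
    idx = {sp: ids.index(sp) for sp in members}
    return [
        float(values[idx[a], idx[b]])
        for a, b in itertools.combinations(members, 2)
    ]


def two_sample_t(
    a: Sequence[float],
    b: Sequence[float],
    statistic_name: str = "value",
    group_labels: tuple[str, str] = ("a", "b"),
) -> CladeComparisonResult:
    """Pooled-variance two-sided Student t-test on two groups of values."""
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a, ddof=1) + np.var(b, ddof=1) == 0.0:
        raise ValueError("zero pooled variance: t statistic undefined")
    res = scipy.stats.ttest_ind(a, b, equal_var=True)
    df = len(a) + len(b) - 2
    return CladeComparisonResult(
        statistic_name=statistic_name,
        group_values=(a, b),
        t=float(res.statistic),
        df=df,
        p_parametric=float(res.pvalue),
        group_labels=group_labels,
    )


def _t_from_matrix(
    values: np.ndarray, members_a: np.ndarray, members_b: np.ndarray
) -> float:
    """Pooled t of within-group upper-triangle values, nan when degenerate."""
    sub_a = values[np.ix_(members_a, members_a)]
    sub_b = values[np.ix_(members_b, members_b)]
    va = sub_a[np.triu_indices(len(members_a), k=1)]
    vb = sub_b[np.triu_indices(len(members_b), k=1)]
    n1, n2 = va.size, vb.size
    s2 = (
        (n1 - 1) * va.var(ddof=1) + (n2 - 1) * vb.var(ddof=1)
    ) / (n1 + n2 - 2)
    if s2 <= 0.0:
        return float("nan")
    return float((va.mean() - vb.mean()) / np.sqrt(s2 * (1.0 / n1 + 1.0 / n2)))


def permutation_test(
    M,
    clades: CladeAssignment,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    statistic_name: str = "value",
) -> CladeComparisonResult:
    """Species-label permutation null for the two-clade contrast.

    The observed pooled t compares within-clade pairwise values between the
    two clades.  Under the null, clade labels are reshuffled across species
    (group sizes preserved), the within-clade pairwise values are rebuilt
    from the matrix, and t recomputed.  Empirical two-sided
    p = (1 + #{|t*| >= |t_obs|}) / (1 + n_permutations).  Permuted
    labelings with degenerate (zero pooled variance) t are counted as
    exceedances, which is conservative.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    labels = clades.labels()
    if len(labels) != 2:
        raise ValueError(f"need exactly two clade labels, got {labels}")
    la, lb = labels
    vals_a = within_clade_pairs(M, clades, la)
    vals_b = within_clade_pairs(M, clades, lb)
    observed = two_sample_t(vals_a, vals_b, statistic_name, (la, lb))

    values, ids = _matrix_and_ids(M)
    species = sorted(set(clades.species_in(la) + clades.species_in(lb)))
    idx = np.array([ids.index(sp) for sp in species])
    n_a = len(clades.species_in(la))
    rng = np.random.default_rng(seed)
    t_abs = abs(observed.t)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(idx)
        t_star = _t_from_matrix(values, perm[:n_a], perm[n_a:])
        if np.isnan(t_star) or abs(t_star) >= t_abs:
            exceed += 1
    observed.p_permutation = (1.0 + exceed) / (1.0 + n_permutations)
    observed.n_permutations = n_permutations
    observed.seed = seed
    return observed


def write_comparison(result: CladeComparisonResult, csv_path: str | Path,
                     txt_path: str | Path | None = None) -> None:
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["statistic", "clade_1", "clade_2", "n_pairs_1", "n_pairs_2",
             "mean_1", "mean_2", "t", "df", "p_parametric", "p_permutation",
             "n_permutations", "seed"]
        )
        g1, g2 = result.group_values
        w.writerow(
            [result.statistic_name, *result.group_labels, len(g1), len(g2),
             f"{np.mean(g1):.6g}", f"{np.mean(g2):.6g}", f"{result.t:.6g}",
             result.df, f"{result.p_parametric:.6g}",
             "" if result.p_permutation is None else f"{result.p_permutation:.6g}",
             result.n_permutations, result.seed if result.seed is not None else ""]
        )
    if txt_path is not None:
        Path(txt_path).write_text(result.report() + "\n")
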
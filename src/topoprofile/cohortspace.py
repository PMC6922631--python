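"""Cohort space: placing individual profiles among cohort-level profiles.

Each profile lives in a 5-D space spanned by its descriptor sums (centrality,
segregation, network proximity, cortical proximity, constant progression).
Individuals are assigned to the nearest cohort profile by Euclidean distance;
an individual closer to another cohort's profile than to their own is an
outlier. A three-cohort layout admits barycentric (ternary) coordinates via
normalized inverse distances, and distances to the own-cohort profile can be
correlated with clinical features.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .profile import TopologicalProfile, sparsify

log = logging.getLogger(__name__)


def descriptor_coords(profile: TopologicalProfile, sparse: bool = True) -> np.ndarray:
    """5-vector of descriptor sums (sparsified by default)."""
    prof = profile if profile.beta_sparse is not None else sparsify(profile)
    if sparse:
        return prof.descriptor_sums.to_numpy(float)
    from .profile import _descriptor_sums

    return _descriptor_sums(prof.beta).to_numpy(float)


@dataclass
class CohortSpaceResult:
    """Per-subject coordinates, distances, assignments and outlier flags."""

    coords: pd.DataFrame                  # subjects x 5
    cohort_coords: pd.DataFrame           # cohorts x 5
    distances: pd.DataFrame               # subjects x cohorts
    assigned: pd.Series
    own: pd.Series
    outlier: pd.Series
    ternary: pd.DataFrame | None = field(default=None)

    def to_csv(self, path) -> None:
        out = self.coords.copy()
        out.columns = [f"coord_{c}" for c in out.columns]
        for c in self.distances.columns:
            out[f"dist_{c}"] = self.distances[c]
        out["own"] = self.own
        out["assigned"] = self.assigned
        out["outlier"] = self.outlier
        if self.ternary is not None:
            for c in self.ternary.columns:
                out[f"ternary_{c}"] = self.ternary[c]
        out.rename_axis("subject").to_csv(path)


def distance_to_cohorts(individual, cohorts) -> np.ndarray:
    """Euclidean distances between an individual's 5-vector and each cohort's."""
    x = (
        descriptor_coords(individual)
        if isinstance(individual, TopologicalProfile)
        else np.asarray(individual, float)
    )
    out = np.empty(len(cohorts))
    for k, c in enumerate(cohorts):
        y = descriptor_coords(c) if isinstance(c, TopologicalProfile) else np.asarray(c, float)
        out[k] = float(np.linalg.norm(x - y))
    return out


def assign_and_flag(
    individual_coords: pd.DataFrame,
    cohort_coords: pd.DataFrame,
    own_labels: pd.Series,
    with_ternary: bool | None = None,
) -> CohortSpaceResult:
    """Nearest-cohort assignment with outlier flags.

    Distance ties resolve to the subject's own cohort when it is among the
    tied minima, otherwise to the lowest cohort index (with a warning).
    """
    if len(cohort_coords) < 2:
        raise DataError("need at least 2 cohort profiles")
    cohorts = list(cohort_coords.index)
    X = individual_coords.to_numpy(float)
    C = cohort_coords.to_numpy(float)
    D = np.linalg.norm(X[:, None, :] - C[None, :, :], axis=2)
    distances = pd.DataFrame(D, index=individual_coords.index, columns=cohorts)

    assigned = []
    for i, subj in enumerate(individual_coords.index):
        row = D[i]
        best = row.min()
        tied = [cohorts[k] for k in np.where(np.isclose(row, best))[0]]
        own = own_labels.loc[subj]
        if len(tied) > 1:
            if own in tied:
                assigned.append(own)
            else:
                log.warning("distance tie for subject %r; taking lowest cohort index", subj)
                assigned.append(tied[0])
        else:
            assigned.append(tied[0])
    assigned = pd.Series(assigned, index=individual_coords.index, name="assigned")
    outlier = assigned != own_labels.reindex(assigned.index)

    ternary = None
    if with_ternary or (with_ternary is None and len(cohorts) == 3):
        try:
            ternary = pd.DataFrame(
                [ternary_coords(D[i]) for i in range(len(D))],
                index=individual_coords.index,
                columns=cohorts,
            )
        except DataError as exc:
            log.warning("ternary coordinates unavailable: %s", exc)
    return CohortSpaceResult(
        coords=individual_coords,
        cohort_coords=cohort_coords,
        distances=distances,
        assigned=assigned,
        own=own_labels.reindex(assigned.index),
        outlier=outlier,
        ternary=ternary,
    )


def confusion_matrix(result: CohortSpaceResult) -> pd.DataFrame:
    """Rows = true cohort, columns = assigned cohort, entries in percent.

    Rows sum to 100; an empty cohort yields a NaN row.
    """
    cohorts = list(result.cohort_coords.index)
    table = pd.DataFrame(np.nan, index=cohorts, columns=cohorts)
    for true in cohorts:
        mask = result.own == true
        n = int(mask.sum())
        if n == 0:
            log.warning("cohort %r has no individuals; confusion row is NaN", true)
            continue
        counts = result.assigned[mask].value_counts()
        for pred in cohorts:
            table.loc[true, pred] = 100.0 * counts.get(pred, 0) / n
    return table


def ternary_coords(distances) -> np.ndarray:
    """Barycentric coordinates from three cohort distances.

    coordinate_i = (1/d_i) / sum_k (1/d_k); a zero distance maps to the
    corresponding corner. Two zero distances mean coincident cohort profiles,
    which is an error.
    """
    d = np.asarray(distances, float)
    if d.shape != (3,):
        raise DataError("ternary coordinates need exactly 3 cohort distances")
    if (d < 0).any():
        raise DataError("negative distance")
    zero = d == 0
    if zero.sum() >= 2:
        raise DataError("two cohort profiles coincide with the individual")
    if zero.any():
        out = np.zeros(3)
        out[np.argmax(zero)] = 1.0
        return out
    inv = 1.0 / d
    return inv / inv.sum()


def correlate_feature(distances, feature):
    """Pearson correlation between own-cohort distances and a clinical feature.

    Pairs with missing values are dropped; returns (r, p) or (nan, nan) with
    a warning when either input has zero variance or fewer than 3 pairs.
    """
    d = pd.Series(np.asarray(distances, float))
    f = pd.Series(np.asarray(feature, float))
    ok = d.notna() & f.notna()
    d, f = d[ok], f[ok]
    if len(d) < 3:
        raise DataError("need at least 3 paired observations")
    if d.std() == 0 or f.std() == 0:
        log.warning("zero-variance input; correlation undefined")
        return np.nan, np.nan
    r, p = stats.pearsonr(d, f)
    return float(r), float(p)
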
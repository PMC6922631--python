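"""Synthetic study generator: connectomes, design matrices and cohorts with
known ground truth.

The generator composes the same forward model the estimator inverts: a
mirrored random-geometric connectome yields a design matrix Sigma; a chosen
non-negative weight vector beta_true fixes per-region maximal atrophy rates
Y* = Sigma beta_true (min-max scaled); each region follows a logistic
trajectory whose maximal slope equals its rate (the logistic's max slope has
the closed form A k / 4, which keeps the rate extraction analytically
testable); subjects observe the trajectories through latent time shifts,
per-subject offsets and Gaussian noise.

Default study conditions: 82 lateralized regions (41 bilateral pairs), 50
subjects with 4 annual visits, time shifts of sd 2 years, observation noise
of 0.05 z-units and subject offsets of 0.05 z-units -- a short-interval
volumetric cohort of the size typical for single-site imaging studies.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .cohort import LongitudinalCohort, ZScoreCohort
from .connectome import Connectome, average_connectomes, spatial_distance_matrix
from .errors import DataError
from .metrics import METRIC_NAMES, build_design_matrix, compute_node_metrics

log = logging.getLogger(__name__)

#: two-mechanism default: centrality (betweenness) plus network proximity
DEFAULT_BETA = {"betweenness": 0.4, "shortest_path": 0.6}


def beta_vector(spec_like) -> np.ndarray:
    """A 9-vector from a {metric: weight} mapping or an array."""
    if isinstance(spec_like, dict):
        out = np.zeros(len(METRIC_NAMES))
        for name, w in spec_like.items():
            out[METRIC_NAMES.index(name)] = float(w)
        return out
    arr = np.asarray(spec_like, float)
    if arr.shape != (len(METRIC_NAMES),):
        raise DataError("beta_true must have nine entries")
    return arr


@dataclass
class SyntheticSpec:
    """Study conditions for :func:`make_cohort`."""

    n_regions: int = 82                       # lateralized count, even
    beta_true: np.ndarray = field(default_factory=lambda: beta_vector(DEFAULT_BETA))
    n_subjects: int = 50
    n_visits: int = 4
    visit_spacing: float = 1.0                # years
    baseline_spread: float = 5.0              # half-width of disease-time entry points
    shift_sd: float = 2.0                     # years
    noise_sd: float = 0.05                    # z-units
    offset_sd: float = 0.05                   # z-units
    amplitude: float = 3.0                    # trajectory range, z-units
    rate_scale: float = 1.0                   # max slope of the fastest region, z/yr
    normalize_beta: bool = True               # rescale beta so rates span [0, 1]
    seed: int = 0

    def __post_init__(self):
        self.beta_true = beta_vector(self.beta_true)
        if (self.beta_true < 0).any():
            raise DataError("beta_true must be non-negative")
        if self.n_subjects < 2:
            raise DataError("need at least 2 subjects")


def make_connectome(
    V: int = 82, density: float = 0.3, spatial_decay: float = 40.0, seed: int = 0,
    weight_heterogeneity: float = 2.0,
) -> tuple[Connectome, RegionAtlas]:
    """Mirrored random-geometric connectome plus its atlas.

    V/2 barycenters are placed in one hemisphere (x > 0) and mirrored; edge
    weights decay exponentially with Euclidean distance, modulated by
    log-normal edge heterogeneity (streamline-count-like weight spread, which
    decouples network distance from pure spatial distance), and the sparsity
    mask is made invariant under the left/right pairing permutation, so the
    whole weight matrix is hemisphere-symmetric. Disconnected draws are
    retried up to 10 times.
    """
    if V % 2:
        raise DataError("V must be even (left/right pairing)")
    if not 0 < density <= 1:
        raise DataError("density must lie in (0, 1]")
    half = V // 2
    rng = np.random.default_rng(seed)
    for attempt in range(10):
        right = np.column_stack(
            [
                rng.uniform(10, 70, half),
                rng.uniform(-60, 60, half),
                rng.uniform(-40, 50, half),
            ]
        )
        left = right * np.array([-1.0, 1.0, 1.0])
        coords = np.vstack([left, right])
        names = [f"region{i:02d}_L" for i in range(half)] + [
            f"region{i:02d}_R" for i in range(half)
        ]
        pairs = [f"region{i:02d}" for i in range(half)] * 2
        atlas = RegionAtlas(
            names=tuple(names),
            hemisphere=tuple(["left"] * half + ["right"] * half),
            pair_id=tuple(pairs),
            coords=coords,
        )
        dist = spatial_distance_matrix(atlas)
        mask = rng.random((V, V)) < density
        mask = np.triu(mask, 1)
        mask = mask | mask.T
        perm = atlas.lr_permutation()
        mask = mask | mask[np.ix_(perm, perm)]   # hemisphere-symmetric sparsity
        g = rng.normal(0.0, weight_heterogeneity, (V, V))
        g = (g + g.T) / 2.0
        g = (g + g[np.ix_(perm, perm)]) / 2.0    # hemisphere-symmetric spread
        w = np.exp(-dist / spatial_decay) * np.exp(g) * mask
        if w.max() > 0:
            w = w / w.max()
        np.fill_diagonal(w, 0.0)
        if nx.is_connected(nx.from_numpy_array(w)):
            conn = average_connectomes([w], atlas=atlas)
            return conn, atlas
    raise DataError("could not generate a connected connectome in 10 attempts")


def make_design(V: int = 82, density: float = 0.3, spatial_decay: float = 40.0,
                seed: int = 0, epicenter: str | None = None):
    """Connectome + atlas + design matrix in one call (epicenter defaults to
    the first bilateral label)."""
    conn, atlas = make_connectome(V, density, spatial_decay, seed)
    raw = compute_node_metrics(conn)
    dist = spatial_distance_matrix(atlas)
    epi = epicenter or atlas.bilateral_labels[0]
    design = build_design_matrix(raw, conn, dist, epi, atlas)
    return conn, atlas, design


def logistic_family(rates: np.ndarray, amplitude: float):
    """Per-region logistic trajectories with prescribed maximal slopes.

    f_v(tau) = A / (1 + exp(-k_v tau)) - A/2 with k_v = 4 r_v / A, so
    max_tau f_v'(tau) = A k_v / 4 = r_v exactly; r_v = 0 gives a flat line.
    """
    k = 4.0 * np.asarray(rates, float) / amplitude

    def f(tau):
        t = np.asarray(tau, float)[..., None]
        return amplitude / (1.0 + np.exp(-k[None, :] * t)) - amplitude / 2.0

    def fprime(tau):
        t = np.asarray(tau, float)[..., None]
        e = np.exp(-k[None, :] * t)
        return amplitude * k[None, :] * e / (1.0 + e) ** 2

    return f, fprime, k


def make_cohort(spec: SyntheticSpec, sigma) -> tuple[ZScoreCohort, dict]:
    """Generate a longitudinal z-score cohort from a design matrix.

    Returns the cohort plus the ground-truth record (scaled rates, shifts,
    beta_true, logistic steepness).
    """
    from .profile import minmax_scale

    sig = sigma.sigma if hasattr(sigma, "sigma") else pd.DataFrame(
        np.asarray(sigma, float), columns=list(METRIC_NAMES)
    )
    if sig.shape[1] != len(spec.beta_true):
        raise DataError("design matrix width does not match beta_true")
    regions = list(sig.index)
    A = sig.to_numpy(float)
    names = list(sig.columns)
    beta_true = spec.beta_true.copy()
    raw = A @ beta_true
    lo, hi = raw.min(), raw.max()
    if spec.normalize_beta and hi - lo > 0:
        # rescale so the noiseless rate field spans [0, 1] exactly; the
        # min-max step of the estimator is then the identity and beta_true
        # itself is the identifiable target (the shift lands on the constant
        # column, clipped at zero if the original constant cannot absorb it)
        r = hi - lo
        beta_true = beta_true / r
        ci = names.index("constant")
        beta_true[ci] -= lo / r
        if beta_true[ci] < 0:
            log.debug("constant weight clipped at 0 during normalization "
                      "(%.3f)", beta_true[ci])
            beta_true[ci] = 0.0
        raw = A @ beta_true
    Y_star = minmax_scale(raw)
    if not (Y_star > 0).any():
        log.warning("all-zero beta_true; cohort will be flat")
    from scipy.optimize import nnls

    beta_ident, _ = nnls(A, Y_star)
    rates = Y_star * spec.rate_scale
    f, _, k = logistic_family(rates, spec.amplitude)

    rng = np.random.default_rng(spec.seed)
    shifts = rng.normal(0.0, spec.shift_sd, spec.n_subjects)
    shifts -= shifts.mean()
    base = rng.uniform(-spec.baseline_spread, spec.baseline_spread, spec.n_subjects)
    offsets = rng.normal(0.0, spec.offset_sd, (spec.n_subjects, len(regions)))

    ids = [f"S{j:04d}" for j in range(spec.n_subjects)]
    rows, index = [], []
    for j, s in enumerate(ids):
        visit_tau = base[j] + spec.visit_spacing * np.arange(spec.n_visits)
        ages = visit_tau + shifts[j]            # observed age = disease time + shift
        values = f(visit_tau) + offsets[j][None, :]
        values = values + rng.normal(0.0, spec.noise_sd, values.shape)
        for kv, age in enumerate(ages):
            rows.append(values[kv])
            index.append((s, float(age)))
    volumes = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["subject", "age"]),
        columns=regions,
    )
    cohort = ZScoreCohort(
        volumes=volumes,
        covariates=pd.DataFrame(index=volumes.index),
        groups=pd.Series("patient", index=ids),
        control_stats=pd.DataFrame(
            {"mean": 0.0, "sd": 1.0}, index=regions
        ),
    )
    truth = {
        "beta_true": beta_true,
        "beta_identifiable": pd.Series(beta_ident, index=names),
        "rates": pd.Series(rates, index=regions),
        "Y_star": pd.Series(Y_star, index=regions),
        "shifts": pd.Series(shifts, index=ids),
        "steepness": pd.Series(k, index=regions),
        "offsets": pd.DataFrame(offsets, index=ids, columns=regions),
    }
    return cohort, truth


def to_volume_cohort(
    z: ZScoreCohort,
    atlas: RegionAtlas | None = None,
    n_controls: int = 20,
    base_volume: float = 5000.0,
    control_sd: float = 50.0,
    tiv_slope: float = 0.5,
    seed: int = 0,
) -> LongitudinalCohort:
    """Wrap a z-score cohort back into raw volumes with nuisance structure.

    Patients' volumes are base - z * control_sd plus a TIV effect; a flat
    control group with the same noise scale is appended, so the preprocessing
    chain (nuisance adjustment, z-scoring against controls) can be exercised
    end to end and should approximately restore the input z-scores. When an
    atlas is given, each bilateral column is expanded to its two lateralized
    member regions (identical underlying signal), matching the on-disk layout
    of real volumetry tables.
    """
    rng = np.random.default_rng(seed)
    if atlas is not None:
        expand = {atlas.names[i]: pair for pair in atlas.bilateral_labels
                  for i in atlas.members_of(pair)}
        regions = list(expand)
    else:
        expand = {r: r for r in z.regions}
        regions = z.regions
    rows, index, cov_rows = [], [], []
    for s in z.subjects:
        tiv = rng.normal(1500.0, 100.0)
        block = z.volumes.loc[s]
        for age, zrow in block.iterrows():
            zvals = np.array([zrow[expand[r]] for r in regions], float)
            vol = base_volume - zvals * control_sd + tiv_slope * (tiv - 1500.0)
            rows.append(vol)
            index.append((s, float(age)))
            cov_rows.append((tiv, float(rng.integers(0, 2))))
    ages_seen = z.volumes.index.get_level_values(1)
    ctrl_ids = [f"C{j:04d}" for j in range(n_controls)]
    for s in ctrl_ids:
        tiv = rng.normal(1500.0, 100.0)
        age = float(rng.uniform(ages_seen.min(), ages_seen.max()))
        vol = base_volume + rng.normal(0.0, control_sd, len(regions)) + tiv_slope * (tiv - 1500.0)
        rows.append(vol)
        index.append((s, age))
        cov_rows.append((tiv, float(rng.integers(0, 2))))
    volumes = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["subject", "age"]),
        columns=regions,
    ).sort_index()
    covariates = pd.DataFrame(
        cov_rows, columns=["tiv", "sex"],
        index=pd.MultiIndex.from_tuples(index, names=["subject", "age"]),
    ).sort_index()
    groups = pd.Series(
        {**{s: z.groups.loc[s] for s in z.subjects}, **{s: "control" for s in ctrl_ids}}
    )
    return LongitudinalCohort(volumes=volumes, covariates=covariates, groups=groups)


def write_cohort_csv(cohort: LongitudinalCohort, path) -> None:
    """Long-format CSV matching the default reader schema."""
    records = []
    has_cov = len(cohort.covariates.columns) > 0
    for (s, age), row in cohort.volumes.iterrows():
        cov = cohort.covariates.loc[(s, age)] if has_cov else None
        for region, value in row.items():
            rec = {
                "subject": s,
                "age": age,
                "region": region,
                "volume": value,
                "group": cohort.groups.loc[s],
            }
            if cov is not None:
                rec.update({c: cov[c] for c in cohort.covariates.columns})
            records.append(rec)
    pd.DataFrame(records).to_csv(path, index=False)
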
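"""Longitudinal volumetry: table reading and the three preprocessing steps.

A cohort is a long-format table of regional gray-matter volumes turned into a
visits x regions matrix, together with per-visit nuisance covariates (total
intracranial volume, sex, age) and a control/patient label per subject.
Preprocessing mirrors standard volumetric practice:

1. regress nuisance covariates out of each region (coefficients estimated on
   controls by default, residuals applied to everyone);
2. drop unwanted regions and average each left/right pair, halving the
   region count;
3. standardize against the control population, oriented so that larger
   values mean more atrophy.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .errors import DataError, SchemaError

log = logging.getLogger(__name__)

#: default long-format column mapping for :func:`read_cohort_table`
DEFAULT_SCHEMA = {
    "subject": "subject",
    "age": "age",
    "region": "region",
    "value": "volume",
    "group": "group",
    "covariates": {"tiv": "tiv", "sex": "sex"},
}


@dataclass
class LongitudinalCohort:
    """Visits x regions volume matrix plus covariates and group labels.

    ``volumes`` is indexed by a (subject, age) MultiIndex sorted by subject
    then age; ``covariates`` shares that index; ``groups`` maps subject id to
    ``control`` or ``patient``.
    """

    volumes: pd.DataFrame
    covariates: pd.DataFrame
    groups: pd.Series
    diagnosis: pd.Series | None = None

    def __post_init__(self):
        idx = self.volumes.index
        if idx.nlevels != 2:
            raise DataError("volumes must be indexed by (subject, age)")
        ages = pd.Series(idx.get_level_values(1), dtype=float)
        subj = pd.Series(idx.get_level_values(0))
        for s, a in ages.groupby(subj.values):
            if not a.is_monotonic_increasing or a.duplicated().any():
                raise DataError(f"visit ages not strictly increasing for subject {s!r}")
        missing = set(subj.unique()) - set(self.groups.index)
        if missing:
            raise DataError(f"subjects without group label: {sorted(missing)[:5]}")

    @property
    def subjects(self) -> list:
        return list(dict.fromkeys(self.volumes.index.get_level_values(0)))

    @property
    def regions(self) -> list:
        return list(self.volumes.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def visit_ages(self, subject) -> np.ndarray:
        return self.volumes.loc[subject].index.to_numpy(float)

    def control_mask(self) -> pd.Series:
        """Boolean per visit row: does it belong to a control subject."""
        subj = self.volumes.index.get_level_values(0)
        return pd.Series(
            self.groups.reindex(subj).to_numpy() == "control",
            index=self.volumes.index,
        )

    def subset(self, subjects) -> "LongitudinalCohort":
        keep = [s for s in self.subjects if s in set(subjects)]
        vol = self.volumes.loc[keep]
        cov = self.covariates.loc[vol.index] if len(self.covariates) else self.covariates
        return replace(
            self,
            volumes=vol,
            covariates=cov,
            groups=self.groups.loc[keep],
            diagnosis=None if self.diagnosis is None else self.diagnosis.loc[keep],
        )


@dataclass
class ZScoreCohort(LongitudinalCohort):
    """Same layout as :class:`LongitudinalCohort`, values are atrophy z-scores.

    ``control_stats`` holds the per-region mean and sd of the control
    population the scores were computed against.
    """

    control_stats: pd.DataFrame = field(default_factory=pd.DataFrame)


def read_cohort_table(path, schema: dict | None = None, sep: str = ",") -> LongitudinalCohort:
    """Parse a delimited cohort file into a :class:`LongitudinalCohort`.

    The schema maps logical names (subject, age, region, value, group, and a
    ``covariates`` sub-mapping) onto the file's column names. Rows are sorted
    by subject then age; duplicate (subject, age, region) rows are an error.
    Long format (one row per subject/visit/region) is the default; set
    ``schema["format"] = "wide"`` for one row per visit with one column per
    region (every column not otherwise mapped is taken as a region).
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, sep=sep)
    cov_map = schema.get("covariates", {}) or {}
    if schema.get("format") == "wide":
        reserved = {schema[k] for k in ("subject", "age", "group")}
        reserved |= set(cov_map.values())
        diag_col = schema.get("diagnosis")
        if diag_col:
            reserved.add(diag_col)
        regions = [c for c in df.columns if c not in reserved]
        if not regions:
            raise SchemaError("wide cohort table has no region columns")
        df = df.melt(
            id_vars=[c for c in df.columns if c in reserved],
            value_vars=regions,
            var_name=schema["region"],
            value_name=schema["value"],
        )
    needed = [schema[k] for k in ("subject", "age", "region", "value", "group")]
    needed += list(cov_map.values())
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing columns: {missing}")

    sub, age = schema["subject"], schema["age"]
    reg, val = schema["region"], schema["value"]
    df[age] = df[age].astype(float)
    if df.duplicated([sub, age, reg]).any():
        dup = df[df.duplicated([sub, age, reg])].iloc[0]
        raise DataError(
            f"duplicate measurement for subject {dup[sub]!r} age {dup[age]} "
            f"region {dup[reg]!r}"
        )
    df = df.sort_values([sub, age], kind="stable")
    volumes = df.pivot(index=[sub, age], columns=reg, values=val).sort_index()
    volumes.index.names = ["subject", "age"]
    volumes.columns.name = None

    per_visit = df.drop_duplicates([sub, age]).set_index([sub, age]).sort_index()
    per_visit.index.names = ["subject", "age"]
    cov = pd.DataFrame(index=volumes.index)
    for logical, col in cov_map.items():
        series = per_visit[col]
        if series.dtype == object:
            codes, uniques = pd.factorize(series.astype(str).sort_values().unique())
            mapping = dict(zip(uniques, codes))
            series = series.astype(str).map(mapping).astype(float)
        cov[logical] = series.astype(float).reindex(volumes.index)

    groups = per_visit.groupby(level=0)[schema["group"]].first().astype(str)
    bad = set(groups.unique()) - {"control", "patient"}
    if bad:
        raise DataError(f"group labels must be control/patient, got {sorted(bad)}")
    diagnosis = None
    diag_col = schema.get("diagnosis")
    if diag_col and diag_col in per_visit.columns:
        diagnosis = per_visit.groupby(level=0)[diag_col].first().astype(str)
    return LongitudinalCohort(volumes, cov, groups, diagnosis)


def _covariate_design(cohort: LongitudinalCohort, covariate_set) -> pd.DataFrame:
    cols = {}
    for name in covariate_set:
        if name == "age" and "age" not in cohort.covariates.columns:
            cols["age"] = cohort.volumes.index.get_level_values(1).to_numpy(float)
        elif name in cohort.covariates.columns:
            cols[name] = cohort.covariates[name].to_numpy(float)
        else:
            raise SchemaError(f"covariate {name!r} not available")
    return pd.DataFrame(cols, index=cohort.volumes.index)


def adjust_nuisance(
    cohort: LongitudinalCohort,
    covariate_set=("tiv", "sex", "age"),
    fit_on: str = "control",
) -> LongitudinalCohort:
    """Regress nuisance covariates out of every region's volumes.

    Coefficients are estimated by ordinary least squares on the ``fit_on``
    subset (``control`` by default, ``all`` optionally) and residuals plus the
    control-subset intercept replace the volumes for everyone, so adjusted
    volumes are uncorrelated with the covariates on the fitting subset.
    """
    if not covariate_set:
        return cohort
    design = _covariate_design(cohort, covariate_set)
    nan_rows = design.isna().any(axis=1)
    if nan_rows.any():
        log.warning("dropping %d visits with missing covariates", int(nan_rows.sum()))
        keep = ~nan_rows
        cohort = replace(
            cohort,
            volumes=cohort.volumes[keep.values],
            covariates=cohort.covariates[keep.values],
        )
        design = design[keep.values]

    fit_mask = (
        cohort.control_mask().to_numpy()
        if fit_on == "control"
        else np.ones(len(design), bool)
    )
    if fit_mask.sum() < design.shape[1] + 1:
        raise DataError("too few fitting rows for nuisance regression")

    X = design.to_numpy(float)
    X_fit = X[fit_mask]
    center = X_fit.mean(axis=0)
    Xc = X - center
    Xc_fit = Xc[fit_mask]
    rank = np.linalg.matrix_rank(Xc_fit)
    if rank < Xc_fit.shape[1]:
        # name the offending columns via near-zero diagonal of R in a QR
        _, r = np.linalg.qr(Xc_fit)
        diag = np.abs(np.diag(r))
        bad = [design.columns[i] for i in np.where(diag < 1e-10 * diag.max())[0]]
        raise DataError(f"collinear covariate columns: {bad or list(design.columns)}")

    Yv = cohort.volumes.to_numpy(float)
    coef, *_ = np.linalg.lstsq(Xc_fit, Yv[fit_mask], rcond=None)
    intercept = Yv[fit_mask].mean(axis=0)
    adjusted = Yv - Xc @ coef
    adjusted = adjusted - adjusted[fit_mask].mean(axis=0) + intercept
    out = pd.DataFrame(adjusted, index=cohort.volumes.index, columns=cohort.volumes.columns)
    return replace(cohort, volumes=out)


def select_and_symmetrize(
    cohort: LongitudinalCohort, atlas: RegionAtlas, drop_list=()
) -> LongitudinalCohort:
    """Drop regions, then replace each bilateral pair by its mean volume.

    Output columns are pair labels (midline regions keep their name), ordered
    as in the atlas. Works on raw and z-scored cohorts alike.
    """
    drop = set(drop_list)
    unknown = drop - set(atlas.names)
    if unknown:
        raise DataError(f"drop_list regions not in atlas: {sorted(unknown)}")
    missing = [n for n in atlas.names if n not in cohort.volumes.columns and n not in drop]
    if missing:
        raise DataError(f"cohort lacks atlas regions: {missing[:5]}")

    cols = {}
    for pair in atlas.bilateral_labels:
        names = [atlas.names[i] for i in atlas.members_of(pair)]
        kept = [n for n in names if n not in drop]
        if not kept:
            continue
        cols[pair] = cohort.volumes[kept].mean(axis=1)
    out = pd.DataFrame(cols, index=cohort.volumes.index)
    return replace(cohort, volumes=out)


def zscore_vs_controls(cohort: LongitudinalCohort, control_selector=None) -> ZScoreCohort:
    """Standardize against the control population, oriented toward atrophy.

    For raw volume cohorts z = (control_mean - x) / control_sd, so a volume one
    control sd *below* the control mean scores +1 and progressive tissue loss
    yields increasing trajectories. Re-applying the operation to an already
    oriented :class:`ZScoreCohort` re-standardizes without flipping again, so
    z-scoring is idempotent on its own control subset.
    """
    if control_selector is None:
        mask = cohort.control_mask()
    else:
        subj = cohort.volumes.index.get_level_values(0)
        mask = pd.Series([bool(control_selector(s)) for s in subj], index=cohort.volumes.index)
    ctrl_subjects = set(cohort.volumes.index.get_level_values(0)[mask.to_numpy()])
    if len(ctrl_subjects) < 2:
        raise DataError("need at least 2 control subjects for z-scoring")

    ctrl = cohort.volumes[mask.to_numpy()]
    mean = ctrl.mean(axis=0)
    sd = ctrl.std(axis=0, ddof=1)
    zero = sd[sd <= 0]
    if len(zero):
        raise DataError(f"zero control sd for region(s): {list(zero.index)}")

    if isinstance(cohort, ZScoreCohort):
        z = (cohort.volumes - mean) / sd  # already atrophy-oriented
    else:
        z = (mean - cohort.volumes) / sd
    stats = pd.DataFrame({"mean": mean, "sd": sd})
    return ZScoreCohort(
        volumes=z,
        covariates=cohort.covariates,
        groups=cohort.groups,
        diagnosis=cohort.diagnosis,
        control_stats=stats,
    )


def preprocess(
    cohort: LongitudinalCohort,
    atlas: RegionAtlas,
    covariate_set=("tiv", "sex", "age"),
    drop_list=(),
    fit_on: str = "control",
) -> ZScoreCohort:
    """Convenience composition: adjust -> select/symmetrize -> z-score."""
    adjusted = adjust_nuisance(cohort, covariate_set, fit_on=fit_on)
    bilateral = select_and_symmetrize(adjusted, atlas, drop_list)
    return zscore_vs_controls(bilateral)
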
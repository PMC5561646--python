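"""Long-format container for two longitudinal outcomes plus baseline covariates.

The canonical layout is one row per subject x outcome x visit, because the two
outcomes are typically observed on different visit grids (e.g. a visual-field
index measured semiannually and visual acuity measured annually).  Baseline
covariates are constant within subject and stored once per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LongitudinalDataset",
    "CohortFilterPolicy",
    "CovariateScaling",
    "ValidationError",
    "FormatError",
    "DegenerateInputError",
    "read_long_csv",
    "write_long_csv",
    "standardize_covariates",
    "apply_cohort_filter",
]

OBS_COLUMNS = ["subject_id", "outcome", "time", "value"]


class ValidationError(ValueError):
    """Raised when data violate the dataset invariants."""


class FormatError(ValueError):
    """Raised when an input file does not have the expected layout."""


class DegenerateInputError(ValueError):
    """Raised when an operation receives input it cannot meaningfully process."""


@dataclass(frozen=True)
class CohortFilterPolicy:
    """Analysis-cohort rules applied before model fitting.

    Parameters
    ----------
    max_followup
        Observations later than this many years after the index date are
        removed (attrition guard).
    min_subjects_per_time
        Visit times at which either outcome has fewer subjects than this are
        flagged as unreliable for pointwise (cross-sectional) summaries; the
        observations themselves are kept for likelihood-based fits.
    min_obs_per_outcome
        Subjects with fewer observations than this in either outcome are
        excluded entirely.
    """

    max_followup: float = 7.5
    min_subjects_per_time: int = 30
    min_obs_per_outcome: int = 2

    def __post_init__(self) -> None:
        if self.max_followup <= 0 or self.min_subjects_per_time <= 0 or self.min_obs_per_outcome <= 0:
            raise ValueError("all policy fields must be positive")


@dataclass
class LongitudinalDataset:
    """Validated long-format repeated measures for exactly two outcomes.

    Attributes
    ----------
    obs
        DataFrame with columns ``subject_id, outcome, time, value``, sorted by
        subject, outcome, time.  Times are years since the index date.
    outcome1, outcome2
        The labels playing the roles of outcome 1 and outcome 2 (the
        conditional-correlation thresholds apply to outcome 1's trajectory).
    covariates
        Per-subject baseline covariates, indexed by subject_id.  May have no
        columns for a covariate-free dataset.
    sparse_times
        Mapping outcome -> array of visit times flagged by the cohort filter
        as having too few subjects for pointwise summaries.
    """

    obs: pd.DataFrame
    outcome1: str
    outcome2: str
    covariates: pd.DataFrame
    sparse_times: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_frames(
        cls,
        obs: pd.DataFrame,
        outcome1: str,
        outcome2: str,
        covariates: pd.DataFrame | None = None,
    ) -> "LongitudinalDataset":
        obs = obs[OBS_COLUMNS].copy()
        obs = obs.sort_values(["subject_id", "outcome", "time"], kind="mergesort").reset_index(drop=True)
        if covariates is None:
            covariates = pd.DataFrame(index=pd.Index(obs["subject_id"].unique(), name="subject_id"))
        return cls(obs=obs, outcome1=outcome1, outcome2=outcome2, covariates=covariates)

    def _validate(self) -> None:
        missing = [c for c in OBS_COLUMNS if c not in self.obs.columns]
        if missing:
            raise FormatError(f"observation frame missing columns: {missing}")
        labels = set(self.obs["outcome"].unique())
        expected = {self.outcome1, self.outcome2}
        unknown = labels - expected
        if unknown:
            raise ValidationError(f"unknown outcome labels {sorted(unknown)}; expected {sorted(expected)}")
        if self.obs.duplicated(subset=["subject_id", "outcome", "time"]).any():
            dup = self.obs[self.obs.duplicated(subset=["subject_id", "outcome", "time"], keep=False)]
            key = dup.iloc[0]
            raise ValidationError(
                f"duplicate (subject, outcome, time) row: ({key['subject_id']}, {key['outcome']}, {key['time']})"
            )
        if (self.obs["time"] < 0).any():
            raise ValidationError("negative times are not allowed (time 0 is the index date)")
        if not np.isfinite(self.obs["value"].to_numpy(dtype=float)).all():
            raise ValidationError("non-finite measurement values")
        obs_subjects = set(self.obs["subject_id"].unique())
        cov_subjects = set(self.covariates.index)
        if not obs_subjects <= cov_subjects:
            raise ValidationError("covariate table missing subjects present in observations")

    # -- accessors --------------------------------------------------------

    @property
    def subjects(self) -> list:
        return list(self.covariates.index[self.covariates.index.isin(self.obs["subject_id"].unique())])

    @property
    def n_subjects(self) -> int:
        return self.obs["subject_id"].nunique()

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates.columns)

    def counts_per_outcome(self) -> pd.Series:
        return self.obs.groupby("outcome").size()

    def subject_obs(self, subject, outcome: str) -> pd.DataFrame:
        sel = self.obs[(self.obs["subject_id"] == subject) & (self.obs["outcome"] == outcome)]
        if subject not in set(self.obs["subject_id"].unique()):
            raise KeyError(f"subject {subject!r} not in dataset")
        return sel

    def copy(self) -> "LongitudinalDataset":
        return LongitudinalDataset(
            obs=self.obs.copy(),
            outcome1=self.outcome1,
            outcome2=self.outcome2,
            covariates=self.covariates.copy(),
            sparse_times={k: np.array(v).copy() for k, v in self.sparse_times.items()},
        )


# -- I/O -------------------------------------------------------------------


def read_long_csv(
    path,
    outcome1: str,
    outcome2: str,
    covariate_names: list[str] | None = None,
) -> LongitudinalDataset:
    """Read a long-format CSV: ``subject_id,outcome,time,value[,covariate...]``.

    Covariate columns must be constant within subject; the per-subject value
    is extracted from the rows.  Exactly the two named outcome labels must
    appear in the ``outcome`` column.
    """
    covariate_names = list(covariate_names or [])
    df = pd.read_csv(path)
    missing = [c for c in OBS_COLUMNS + covariate_names if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    df["time"] = pd.to_numeric(df["time"], errors="raise")
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    if covariate_names:
        cov = df.groupby("subject_id")[covariate_names].agg(["min", "max"])
        for name in covariate_names:
            if not np.allclose(
                cov[(name, "min")].to_numpy(dtype=float),
                cov[(name, "max")].to_numpy(dtype=float),
                equal_nan=True,
            ):
                raise ValidationError(f"covariate {name!r} varies within a subject; baseline covariates must be constant")
        covariates = df.groupby("subject_id")[covariate_names].first()
    else:
        covariates = pd.DataFrame(index=pd.Index(df["subject_id"].unique(), name="subject_id"))
    return LongitudinalDataset.from_frames(df, outcome1, outcome2, covariates=covariates)


def write_long_csv(data: LongitudinalDataset, path) -> None:
    """Write the dataset back to the long CSV layout read by :func:`read_long_csv`."""
    out = data.obs.copy()
    if data.covariate_names:
        out = out.join(data.covariates, on="subject_id")
    out.to_csv(path, index=False)


# -- covariate standardization --------------------------------------------


@dataclass(frozen=True)
class CovariateScaling:
    """Record of the per-covariate (mean, sd) used for standardization."""

    means: dict
    sds: dict

    def inverse(self, covariates: pd.DataFrame) -> pd.DataFrame:
        out = covariates.copy()
        for name, mu in self.means.items():
            out[name] = out[name] * self.sds[name] + mu
        return out


def standardize_covariates(
    data: LongitudinalDataset, which: list[str]
) -> tuple[LongitudinalDataset, CovariateScaling]:
    """Center and scale the named continuous covariates to mean 0, variance 1.

    Moments are computed over subjects (one value per subject), with the
    sample (n-1) variance denominator.  Returns the transformed dataset and a
    scaling record sufficient to undo the transformation.
    """
    means, sds = {}, {}
    cov = data.covariates.copy()
    for name in which:
        if name not in cov.columns:
            raise KeyError(f"unknown covariate {name!r}")
        x = cov[name].to_numpy(dtype=float)
        mu = float(np.mean(x))
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        if not np.isfinite(sd) or sd == 0.0:
            raise DegenerateInputError(f"covariate {name!r} has zero variance; cannot standardize")
        cov[name] = (x - mu) / sd
        means[name], sds[name] = mu, sd
    out = data.copy()
    out.covariates = cov
    return out, CovariateScaling(means=means, sds=sds)


# -- cohort filter ---------------------------------------------------------


def apply_cohort_filter(
    data: LongitudinalDataset, policy: CohortFilterPolicy | None = None
) -> tuple[LongitudinalDataset, dict]:
    """Apply the analysis-cohort rules; returns (filtered dataset, report).

    Rules, in order: drop observations past ``max_followup``; drop subjects
    with fewer than ``min_obs_per_outcome`` remaining observations in either
    outcome; flag (not drop) visit times where either outcome has fewer than
    ``min_subjects_per_time`` subjects.  Applying the same policy twice is a
    no-op.
    """
    policy = policy or CohortFilterPolicy()
    obs = data.obs
    late = obs["time"] > policy.max_followup
    n_late = int(late.sum())
    obs = obs[~late]

    counts = obs.groupby(["subject_id", "outcome"]).size().unstack(fill_value=0)
    for oc in (data.outcome1, data.outcome2):
        if oc not in counts.columns:
            counts[oc] = 0
    keep = counts.index[
        (counts[data.outcome1] >= policy.min_obs_per_outcome)
        & (counts[data.outcome2] >= policy.min_obs_per_outcome)
    ]
    n_subj_dropped = data.obs["subject_id"].nunique() - len(keep)
    obs = obs[obs["subject_id"].isin(keep)]
    if obs.empty:
        raise DegenerateInputError("no observations remain after cohort filtering")

    sparse: dict = {}
    per_time = obs.groupby(["outcome", "time"])["subject_id"].nunique()
    for oc in (data.outcome1, data.outcome2):
        if oc in per_time.index.get_level_values(0):
            s = per_time.loc[oc]
            sparse[oc] = np.sort(s.index[s < policy.min_subjects_per_time].to_numpy(dtype=float))
        else:
            sparse[oc] = np.array([])

    filtered = LongitudinalDataset(
        obs=obs.reset_index(drop=True),
        outcome1=data.outcome1,
        outcome2=data.outcome2,
        covariates=data.covariates.loc[data.covariates.index.isin(keep)],
        sparse_times=sparse,
    )
    report = {
        "n_obs_past_max_followup": n_late,
        "n_subjects_below_min_obs": int(n_subj_dropped),
        "n_sparse_times": {oc: int(len(v)) for oc, v in sparse.items()},
        "n_subjects_kept": filtered.n_subjects,
        "n_obs_kept": int(len(filtered.obs)),
    }
    return filtered, report
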
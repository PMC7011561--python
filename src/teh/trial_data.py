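"""Two-arm trial data container, CSV I/O, and arm-balanced random partitions.

The central object is :class:`TrialData`: baseline covariates ``X``, a
randomised binary treatment ``T`` (0 = standard of care, 1 = experimental)
and a binary outcome ``Y`` (1 = adverse event, e.g. death).  Everything in
this package that resamples the trial goes through :func:`make_split_plan`,
which draws a random half/half partition balanced within each treatment arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ColumnSchema",
    "TrialData",
    "SplitPlan",
    "SchemaError",
    "ValidationError",
    "read_trial_csv",
    "write_trial_csv",
    "make_split_plan",
    "make_ratio_split",
]


class SchemaError(ValueError):
    """A required column is missing or the schema is inconsistent."""


class ValidationError(ValueError):
    """The data violate the trial-data contract (non-binary outcome, ...)."""


@dataclass(frozen=True)
class ColumnSchema:
    """Column roles for a delimited trial file.

    Parameters
    ----------
    outcome : str
        Name of the binary outcome column (coded 0/1, 1 = adverse event).
    treatment : str
        Name of the treatment column.
    covariates : tuple of str
        Names of the baseline covariate columns.
    soc_label : object
        The treatment label that denotes standard of care; it is recoded
        to 0, every other (single) label to 1.
    subject_id : str or None
        Optional column with subject labels; row numbers are used if absent.
    delimiter : str
        Field delimiter of the file.
    """

    outcome: str
    treatment: str
    covariates: tuple
    soc_label: object = 0
    subject_id: str | None = None
    delimiter: str = ","


@dataclass
class TrialData:
    """A validated two-arm randomised trial.

    Attributes
    ----------
    subject_id : ndarray
        Opaque per-subject labels.
    X : DataFrame
        n x d baseline covariates; numeric or pandas-categorical columns.
    T : ndarray of int
        Treatment indicator, 0 = standard of care, 1 = experimental.
    Y : ndarray of int
        Binary outcome, 1 = adverse event.
    outcome_orientation : str
        Records that a larger event probability is worse.
    """

    subject_id: np.ndarray
    X: pd.DataFrame
    T: np.ndarray
    Y: np.ndarray
    outcome_orientation: str = "higher_is_worse"

    def __post_init__(self):
        self.subject_id = np.asarray(self.subject_id)
        self.T = np.asarray(self.T)
        self.Y = np.asarray(self.Y)
        self.X = pd.DataFrame(self.X).reset_index(drop=True)
        self._validate()
        self.T = self.T.astype(int)
        self.Y = self.Y.astype(int)

    def _validate(self):
        n = len(self.subject_id)
        if not (len(self.T) == len(self.Y) == len(self.X) == n):
            raise ValidationError(
                "subject_id, T, Y and X must have a common length; got "
                f"{n}, {len(self.T)}, {len(self.Y)}, {len(self.X)}"
            )
        if n == 0:
            raise ValidationError("empty trial")
        for name, v in (("Y", self.Y), ("T", self.T)):
            arr = np.asarray(v)
            if pd.isna(arr).any():
                raise ValidationError(f"missing values in {name}")
            vals = np.unique(arr)
            if not np.isin(vals, [0, 1]).all():
                raise ValidationError(
                    f"{name} must be binary 0/1; found values {vals.tolist()}"
                )
        n_treated = int(np.sum(self.T))
        if n_treated == 0 or n_treated == n:
            raise ValidationError(
                "single-arm data: both treatment arms must be non-empty"
            )
        bad = [c for c in self.X.columns if self.X[c].isna().any()]
        if bad:
            raise ValidationError(
                "covariates contain missing values (complete cases required); "
                f"offending columns: {bad}"
            )

    @property
    def n(self) -> int:
        return len(self.Y)

    @property
    def n_treated(self) -> int:
        return int(np.sum(self.T))

    def subset(self, idx) -> "TrialData":
        """Row subset by positional indices; skips re-validation of arms
        only implicitly (a single-arm subset raises)."""
        idx = np.asarray(idx)
        return TrialData(
            subject_id=self.subject_id[idx],
            X=self.X.iloc[idx],
            T=self.T[idx],
            Y=self.Y[idx],
            outcome_orientation=self.outcome_orientation,
        )

    def to_frame(self, schema: ColumnSchema | None = None) -> pd.DataFrame:
        """Flatten to a single table with recoded 0/1 treatment."""
        out = self.X.copy()
        tcol = schema.treatment if schema else "treatment"
        ycol = schema.outcome if schema else "outcome"
        idcol = (schema.subject_id if schema and schema.subject_id else "subject_id")
        out.insert(0, idcol, self.subject_id)
        out[tcol] = self.T
        out[ycol] = self.Y
        return out


@dataclass(frozen=True)
class SplitPlan:
    """One random partition of the subjects into two halves, balanced by arm."""

    half_a: np.ndarray
    half_b: np.ndarray
    seed: int = field(default=0)

    def __post_init__(self):
        object.__setattr__(self, "half_a", np.asarray(self.half_a, dtype=int))
        object.__setattr__(self, "half_b", np.asarray(self.half_b, dtype=int))


def read_trial_csv(path, schema: ColumnSchema) -> TrialData:
    """Read a delimited trial file and return a validated :class:`TrialData`.

    Treatment labels are recoded so that ``schema.soc_label`` becomes 0 and
    the (single) remaining label becomes 1.  Non-numeric covariates are
    stored as pandas categoricals.
    """
    df = pd.read_csv(path, sep=schema.delimiter)
    required = [schema.outcome, schema.treatment, *schema.covariates]
    if schema.subject_id:
        required.append(schema.subject_id)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns in {path}: {missing}")

    treat_raw = df[schema.treatment]
    labels = pd.unique(treat_raw.dropna())
    if schema.soc_label not in list(labels):
        raise ValidationError(
            f"standard-of-care label {schema.soc_label!r} not found in "
            f"treatment column (labels: {list(labels)})"
        )
    others = [l for l in labels if l != schema.soc_label]
    if len(others) > 1:
        raise ValidationError(
            f"more than two treatment labels: {list(labels)}"
        )
    T = (treat_raw != schema.soc_label).astype(int).to_numpy()

    X = df[list(schema.covariates)].copy()
    for c in X.columns:
        if not pd.api.types.is_numeric_dtype(X[c]):
            X[c] = X[c].astype("category")

    subject_id = (
        df[schema.subject_id].to_numpy()
        if schema.subject_id
        else np.arange(len(df))
    )
    return TrialData(subject_id=subject_id, X=X, T=T, Y=df[schema.outcome].to_numpy())


def write_trial_csv(data: TrialData, path, schema: ColumnSchema | None = None):
    """Round-trip a trial to CSV with the recoded 0/1 treatment."""
    sep = schema.delimiter if schema else ","
    data.to_frame(schema).to_csv(path, sep=sep, index=False)


def _split_arm(idx: np.ndarray, rng: np.random.Generator, extra_to_a: bool):
    """Shuffle one arm and cut it in half; the odd subject goes to the
    side indicated by ``extra_to_a``."""
    perm = rng.permutation(idx)
    n = len(perm)
    cut = (n + 1) // 2 if extra_to_a else n // 2
    return perm[:cut], perm[cut:]


def make_split_plan(data: TrialData, seed: int) -> SplitPlan:
    """Draw a random 50/50 partition balanced within each treatment arm.

    Within each arm, subject counts in the two halves differ by at most 1,
    and the overall half sizes differ by at most 1.  Reproducible for a
    given (data, seed).
    """
    T = data.T
    arm1 = np.flatnonzero(T == 1)
    arm0 = np.flatnonzero(T == 0)
    if len(arm1) < 2 or len(arm0) < 2:
        raise ValidationError(
            "cannot balance a split: each arm needs at least 2 subjects "
            f"(got {len(arm1)} treated, {len(arm0)} untreated)"
        )
    rng = np.random.default_rng(seed)
    # When both arms are odd, the two leftover subjects must land on
    # opposite halves to keep the overall sizes within 1.
    extra1 = bool(rng.integers(2))
    extra0 = (not extra1) if (len(arm0) % 2 and len(arm1) % 2) else bool(rng.integers(2))
    a1, b1 = _split_arm(arm1, rng, extra1)
    a0, b0 = _split_arm(arm0, rng, extra0)
    half_a = np.sort(np.concatenate([a1, a0]))
    half_b = np.sort(np.concatenate([b1, b0]))
    return SplitPlan(half_a=half_a, half_b=half_b, seed=seed)


def make_ratio_split(data: TrialData, ratio: float, seed: int) -> SplitPlan:
    """Unequal partition used only by the split-ratio experiment.

    ``ratio`` is the fraction of each arm assigned to ``half_a``.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    halves_a, halves_b = [], []
    for arm in (1, 0):
        idx = rng.permutation(np.flatnonzero(data.T == arm))
        cut = int(round(ratio * len(idx)))
        cut = min(max(cut, 1), len(idx) - 1)
        halves_a.append(idx[:cut])
        halves_b.append(idx[cut:])
    return SplitPlan(
        half_a=np.sort(np.concatenate(halves_a)),
        half_b=np.sort(np.concatenate(halves_b)),
        seed=seed,
    )
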
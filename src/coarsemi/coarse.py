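"""Data model for coarsened categorical observations.

A coarsened observation of a categorical variable is a non-empty subset of the
variable's sample space that is known to contain the true value.  A singleton
subset is a fully observed value, the full sample space is a completely
missing value, and anything in between is a properly coarsened observation
(e.g. "present" = {focal, substantial} for a three-level pathology score).

This module provides the containers (:class:`SampleSpace`, :class:`CoarseValue`,
:class:`AnalysisDataset`), the three-way classification of observations, the
X/C two-column encoding used by the auxiliary-variable imputation methods, and
a plain-CSV round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleSpace",
    "CoarseValue",
    "AnalysisDataset",
    "EncodedColumns",
    "classify_observation",
    "compatible_labels",
    "coarsening_codes",
    "encode_observed",
    "render_token",
    "parse_token",
    "read_dataset_csv",
    "write_dataset_csv",
]

OutcomeKind = Literal["continuous", "survival"]


@dataclass(frozen=True)
class SampleSpace:
    """Ordered finite sample space of a categorical variable.

    The label order is fixed for the lifetime of an analysis: it defines the
    reference level (first label) and the coefficient ordering of every model
    that involves the variable.
    """

    labels: tuple[str, ...]

    def __init__(self, labels: Iterable[str]):
        labels = tuple(str(l) for l in labels)
        if len(labels) < 2:
            raise ValueError("a sample space needs at least 2 labels")
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate labels in sample space: {labels}")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self.labels

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class CoarseValue:
    """One observation: a non-empty subset of a :class:`SampleSpace`."""

    subset: frozenset
    space: SampleSpace

    def __init__(self, subset: Iterable[str], space: SampleSpace):
        subset = frozenset(str(l) for l in subset)
        if not subset:
            raise ValueError("coarse observation must be a non-empty subset")
        extra = subset - set(space.labels)
        if extra:
            raise ValueError(f"labels {sorted(extra)} outside sample space {space.labels}")
        object.__setattr__(self, "subset", subset)
        object.__setattr__(self, "space", space)

    @property
    def is_observed(self) -> bool:
        return len(self.subset) == 1

    @property
    def is_missing(self) -> bool:
        return len(self.subset) == len(self.space)

    @property
    def is_coarsened(self) -> bool:
        return not (self.is_observed or self.is_missing)

    @property
    def label(self) -> str:
        """The single label of a fully observed value."""
        if not self.is_observed:
            raise ValueError("not a fully observed value")
        return next(iter(self.subset))

    def sorted_labels(self) -> tuple[str, ...]:
        """Members of the subset in sample-space order."""
        return tuple(l for l in self.space.labels if l in self.subset)

    def __contains__(self, label: object) -> bool:
        return label in self.subset


def classify_observation(s: CoarseValue) -> str:
    """Classify an observation as ``"missing"``, ``"observed"`` or ``"coarsened"``.

    The full sample space means completely missing, a single point means
    completely observed, and any other subset is properly coarsened.
    """
    if s.is_missing:
        return "missing"
    if s.is_observed:
        return "observed"
    return "coarsened"


def compatible_labels(s: CoarseValue, space: SampleSpace | None = None) -> list[str]:
    """Labels compatible with the observation, in sample-space order."""
    space = space or s.space
    extra = s.subset - set(space.labels)
    if extra:
        raise ValueError(f"labels {sorted(extra)} outside sample space {space.labels}")
    return [l for l in space.labels if l in s.subset]


def coarsening_codes(x_obs: Sequence[CoarseValue]) -> tuple[np.ndarray, dict]:
    """Integer coarsening-indicator codes for a vector of observations.

    0 = completely missing, 1 = completely observed, and codes 2, 3, ... are
    assigned bijectively to the distinct proper coarsening patterns actually
    present in the data (in order of first appearance).
    """
    codes = np.empty(len(x_obs), dtype=int)
    patterns: dict = {}
    for i, s in enumerate(x_obs):
        kind = classify_observation(s)
        if kind == "missing":
            codes[i] = 0
        elif kind == "observed":
            codes[i] = 1
        else:
            if s.subset not in patterns:
                patterns[s.subset] = 2 + len(patterns)
            codes[i] = patterns[s.subset]
    return codes, {frozenset(k): v for k, v in patterns.items()}


# -- tokens -------------------------------------------------------------------

def render_token(s: CoarseValue, style: str = "pipe") -> str:
    """Render a subset as a string token.

    ``pipe`` style joins the labels with ``|`` (``b|c``); ``braces`` renders
    ``{b,c}`` for display parity with the usual tabular presentation.
    Singletons render as the bare label in both styles.
    """
    labels = s.sorted_labels()
    if len(labels) == 1:
        return labels[0]
    if style == "pipe":
        return "|".join(labels)
    if style == "braces":
        return "{" + ",".join(labels) + "}"
    raise ValueError(f"unknown token style {style!r}")


def parse_token(token: object, space: SampleSpace) -> CoarseValue:
    """Parse a token back to a :class:`CoarseValue`.

    Accepts bare labels, ``b|c`` and ``{b,c}`` forms; an empty/NA token means
    completely missing (the full-space subset).
    """
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return CoarseValue(space.labels, space)
    token = str(token).strip()
    if token == "" or token.upper() in {"NA", "NAN"}:
        return CoarseValue(space.labels, space)
    if token.startswith("{") and token.endswith("}"):
        parts = token[1:-1].split(",")
    elif "|" in token:
        parts = token.split("|")
    else:
        parts = [token]
    return CoarseValue([p.strip() for p in parts], space)


# -- X / C encoding -----------------------------------------------------------

@dataclass
class EncodedColumns:
    """The two-column (X, C) encoding consumed by auxiliary-variable methods.

    ``x_col`` carries the certain information: the label where the observation
    is a singleton, missing otherwise.  ``c_col`` carries the coarsening-level
    information: for any non-missing observation, the token of the coarse
    group the observation belongs to (the observed subset for coarsened rows,
    and for singletons the observed coarse pattern containing the label, if
    one exists in the data).  Completely missing rows are ``NA`` in the
    ``na`` dialect and the full-space token in the ``full_set`` dialect.
    """

    x_col: list
    c_col: list
    c_dialect: str
    space: SampleSpace


def encode_observed(x_obs: Sequence[CoarseValue], c_dialect: str = "na") -> EncodedColumns:
    if c_dialect not in {"na", "full_set"}:
        raise ValueError(f"unknown c dialect {c_dialect!r}")
    if not x_obs:
        raise ValueError("empty observation vector")
    space = x_obs[0].space
    if any(s.space != space for s in x_obs):
        raise ValueError("all observations must share one sample space")

    # coarse groups present in the data; a singleton label maps to the group
    # containing it (group-level C value), provided the mapping is unambiguous
    groups = []
    for s in x_obs:
        if s.is_coarsened and s.subset not in [g for g in groups]:
            groups.append(s.subset)
    label_group: dict = {}
    for g in groups:
        for l in g:
            if l in label_group and label_group[l] != g:
                raise ValueError(
                    f"label {l!r} belongs to multiple coarse patterns; "
                    "a single C column cannot encode this"
                )
            label_group[l] = g

    x_col: list = []
    c_col: list = []
    full = CoarseValue(space.labels, space)
    for s in x_obs:
        if s.is_observed:
            x_col.append(s.label)
            g = label_group.get(s.label)
            c_col.append(
                render_token(CoarseValue(g, space), "braces") if g else s.label
            )
        elif s.is_coarsened:
            x_col.append(None)
            c_col.append(render_token(s, "braces"))
        else:  # missing
            x_col.append(None)
            c_col.append(None if c_dialect == "na" else render_token(full, "braces"))
    return EncodedColumns(x_col=x_col, c_col=c_col, c_dialect=c_dialect, space=space)


# -- dataset ------------------------------------------------------------------

@dataclass
class AnalysisDataset:
    """A dataset for the coarsened-covariate problem.

    One categorical covariate observed as :class:`CoarseValue` entries, a
    matrix of fully observed numeric covariates and a fully observed outcome,
    either continuous (``y``) or right-censored survival (``time``,
    ``status``).
    """

    x: list
    z: pd.DataFrame
    outcome_kind: OutcomeKind
    y: np.ndarray | None = None
    time: np.ndarray | None = None
    status: np.ndarray | None = None
    r: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.x)
        if n < 1:
            raise ValueError("empty dataset")
        space = self.x[0].space
        if any(s.space != space for s in self.x):
            raise ValueError("all observations must share one sample space")
        self.z = pd.DataFrame(self.z)
        if len(self.z) != n:
            raise ValueError("z and x lengths differ")
        if self.z.isna().any().any():
            raise ValueError("z must be fully observed")
        if self.outcome_kind == "continuous":
            if self.y is None:
                raise ValueError("continuous outcome requires y")
            self.y = np.asarray(self.y, dtype=float)
            if self.y.shape != (n,) or np.isnan(self.y).any():
                raise ValueError("y must be a fully observed length-n vector")
        elif self.outcome_kind == "survival":
            if self.time is None or self.status is None:
                raise ValueError("survival outcome requires time and status")
            self.time = np.asarray(self.time, dtype=float)
            self.status = np.asarray(self.status, dtype=int)
            if self.time.shape != (n,) or self.status.shape != (n,):
                raise ValueError("time/status must be length-n vectors")
            if (self.time <= 0).any():
                raise ValueError("time must be positive")
            if not np.isin(self.status, [0, 1]).all():
                raise ValueError("status must be 0/1")
        else:
            raise ValueError(f"unknown outcome kind {self.outcome_kind!r}")
        if self.r is None:
            # derive the indicator from the subsets: 0 missing, 1 observed,
            # 2 properly coarsened
            self.r = np.array([0 if s.is_missing else (1 if s.is_observed else 2)
                               for s in self.x], dtype=int)
        else:
            self.r = np.asarray(self.r, dtype=int)
            if self.r.shape != (n,):
                raise ValueError("r must be a length-n vector")
            for s, ri in zip(self.x, self.r):
                if ri == 1 and not s.is_observed:
                    raise ValueError("r=1 rows must carry singleton observations")
                if ri == 0 and not s.is_missing:
                    raise ValueError("r=0 rows must be completely missing")

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def directly_observed(self) -> np.ndarray:
        """Rows whose X record is directly observed (indicator R = 1).

        A row may carry a singleton subset without being directly observed:
        when the coarse group recorded for it contains a single label (an
        X = a row hit by the coarsening pattern), the auxiliary C column
        identifies the value exactly, but the X column itself is missing.
        Methods that ignore the coarsening information treat every row with
        R != 1 as completely missing.
        """
        return self.r == 1

    @property
    def space(self) -> SampleSpace:
        return self.x[0].space

    def subset_mask(self) -> np.ndarray:
        """Boolean n x K matrix: entry (i, k) true iff label k is compatible."""
        K = len(self.space)
        mask = np.zeros((self.n, K), dtype=bool)
        for i, s in enumerate(self.x):
            for k, l in enumerate(self.space.labels):
                mask[i, k] = l in s.subset
        return mask

    def singleton_codes(self) -> np.ndarray:
        """Label index for fully observed rows, -1 elsewhere."""
        out = np.full(self.n, -1, dtype=int)
        for i, s in enumerate(self.x):
            if s.is_observed:
                out[i] = self.space.index(s.label)
        return out

    def classification_counts(self) -> dict:
        kinds = [classify_observation(s) for s in self.x]
        return {k: kinds.count(k) for k in ("observed", "coarsened", "missing")}

    def to_frame(self, token_style: str = "pipe") -> pd.DataFrame:
        df = pd.DataFrame({"x": [render_token(s, token_style) if not s.is_missing else ""
                                 for s in self.x]})
        for c in self.z.columns:
            df[c] = np.asarray(self.z[c])
        if self.outcome_kind == "continuous":
            df["y"] = self.y
        else:
            df["time"] = self.time
            df["status"] = self.status
        df["r"] = self.r
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, space: SampleSpace,
                   outcome_kind: OutcomeKind) -> "AnalysisDataset":
        x = [parse_token(t, space) for t in df["x"]]
        zcols = [c for c in df.columns
                 if c not in {"x", "x_true", "y", "time", "status", "r"}]
        z = df[zcols].astype(float)
        r = df["r"].to_numpy(int) if "r" in df else None
        if outcome_kind == "continuous":
            return cls(x=x, z=z, outcome_kind=outcome_kind,
                       y=df["y"].to_numpy(float), r=r)
        return cls(x=x, z=z, outcome_kind=outcome_kind,
                   time=df["time"].to_numpy(float),
                   status=df["status"].to_numpy(int), r=r)


def write_dataset_csv(dataset: AnalysisDataset, path, token_style: str = "pipe") -> None:
    dataset.to_frame(token_style).to_csv(path, index=False)


def read_dataset_csv(path, space: SampleSpace, outcome_kind: OutcomeKind) -> AnalysisDataset:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    return AnalysisDataset.from_frame(df, space, outcome_kind)
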
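"""Loading, validation, alignment and splitting of expression + survival data.

Expression matrices are features x samples (log-scale expression assumed),
with a header row of sample ids and the first column holding feature ids.
Survival tables carry one row per sample with a positive follow-up time and
a binary event indicator (1 = death/event observed, 0 = right-censored).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SurvivalTable",
    "Dataset",
    "load_expression",
    "load_survival",
    "align",
    "split",
]


def _sep_for(path: str, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("tsv", "csv"):
            raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")
        return "\t" if dialect == "tsv" else ","
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    return "," if name.endswith(".csv") else "\t"


@dataclass
class ExpressionMatrix:
    """A features x samples real matrix with unique string ids on both axes."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicated feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicated sample ids")
        if len(self.sample_ids) < 2:
            raise ValueError("an expression matrix needs at least 2 samples")
        if np.isnan(self.values).any():
            raise ValueError(
                "missing expression values are not accepted; remove or "
                "complete affected rows upstream (no imputation is performed)"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def feature_values(self, feature: str) -> np.ndarray:
        """Expression of one feature across samples (1-d array)."""
        try:
            i = self.feature_ids.index(feature)
        except ValueError:
            raise KeyError(f"unknown feature {feature!r}") from None
        return self.values[i]

    def subset_features(self, features: list[str]) -> "ExpressionMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in features if f not in idx]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        rows = [idx[f] for f in features]
        return ExpressionMatrix(list(features), list(self.sample_ids), self.values[rows])

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(list(self.feature_ids), list(samples), self.values[:, cols])

    def matrix_for(self, features: list[str]) -> np.ndarray:
        """Samples x features design matrix for the given feature order."""
        return self.subset_features(list(features)).values.T


@dataclass
class SurvivalTable:
    """Per-sample follow-up time (> 0) and event indicator (0/1).

    Extra clinical columns present in the source file are preserved as
    opaque covariates and never interpreted by this package.
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length does not match sample ids")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicated sample ids in survival table")
        if np.isnan(self.time).any() or not (self.time > 0).all():
            raise ValueError("all survival times must be positive")
        ev = np.unique(self.event)
        if not np.isin(ev, [0, 1]).all():
            raise ValueError(f"event indicator must be 0 or 1, found {ev}")
        self.event = self.event.astype(int)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset_samples(self, samples: list[str]) -> "SurvivalTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in samples]
        cov = self.covariates.iloc[rows].reset_index(drop=True) if self.covariates is not None else None
        return SurvivalTable(list(samples), self.time[rows], self.event[rows], cov)


@dataclass
class Dataset:
    """Expression and survival for the same samples, in the same order."""

    expression: ExpressionMatrix
    survival: SurvivalTable

    def __post_init__(self) -> None:
        if self.expression.sample_ids != self.survival.sample_ids:
            raise ValueError("expression and survival sample ids differ or are ordered differently")

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids

    @property
    def n_samples(self) -> int:
        return self.expression.n_samples

    @property
    def n_events(self) -> int:
        return self.survival.n_events

    def subset_samples(self, samples: list[str]) -> "Dataset":
        return Dataset(self.expression.subset_samples(samples), self.survival.subset_samples(samples))


def load_expression(path: str, dialect: str | None = None) -> ExpressionMatrix:
    """Read a features x samples TSV/CSV (gzip accepted).

    Rows sharing a feature id are merged by averaging their expression
    values. Non-numeric cells raise with the offending row and column named.
    """
    sep = _sep_for(path, dialect)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty expression matrix")
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric expression value {df.iat[r, c]!r} "
            f"at feature {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if num.isna().to_numpy().any():
        r, c = np.argwhere(num.isna().to_numpy())[0]
        raise ValueError(f"{path}: missing value at feature {df.index[r]!r}, sample {df.columns[c]!r}")
    if num.index.has_duplicates:
        n_dup = int(num.index.duplicated().sum())
        logger.info("merging %d duplicated feature rows by averaging", n_dup)
        num = num.groupby(level=0, sort=False).mean()
    return ExpressionMatrix.from_frame(num)


def load_survival(path: str, dialect: str | None = None) -> SurvivalTable:
    """Read a survival TSV/CSV with mandatory columns sample_id, time, event."""
    sep = _sep_for(path, dialect)
    df = pd.read_csv(path, sep=sep)
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    extra = [c for c in df.columns if c not in required]
    cov = df[extra].copy() if extra else None
    return SurvivalTable(
        list(df["sample_id"].astype(str)),
        df["time"].to_numpy(dtype=float),
        df["event"].to_numpy(),
        cov,
    )


def align(expr: ExpressionMatrix, surv: SurvivalTable) -> Dataset:
    """Restrict both components to their common samples, in expression order."""
    surv_set = set(surv.sample_ids)
    common = [s for s in expr.sample_ids if s in surv_set]
    if not common:
        raise ValueError("expression and survival share no samples")
    d_expr = expr.n_samples - len(common)
    d_surv = surv.n_samples - len(common)
    if d_expr or d_surv:
        logger.info("align dropped %d expression-only and %d survival-only samples", d_expr, d_surv)
    return Dataset(expr.subset_samples(common), surv.subset_samples(common))


def split(
    ds: Dataset, fraction: float, seed: int, stratify_event: bool = False
) -> tuple[Dataset, Dataset]:
    """Random disjoint partition into parts of round(fraction*n) and the rest.

    A simple random split is the default; ``stratify_event=True`` splits
    within the event and censored groups separately. Both parts must contain
    at least one observed event.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = ds.n_samples
    n_a = int(round(fraction * n))
    if n_a == 0 or n_a == n:
        raise ValueError("split fraction leaves one part empty")
    ids = np.array(ds.sample_ids)
    if stratify_event:
        take: list[int] = []
        for grp in (1, 0):
            idx = np.flatnonzero(ds.survival.event == grp)
            k = int(round(fraction * len(idx)))
            take.extend(rng.permutation(idx)[:k].tolist())
        # adjust to the exact target size with random leftovers
        take_set = set(take)
        rest = [i for i in range(n) if i not in take_set]
        while len(take) < n_a:
            take.append(rest.pop(int(rng.integers(len(rest)))))
        while len(take) > n_a:
            rest.append(take.pop(int(rng.integers(len(take)))))
        part_a = sorted(take)
    else:
        part_a = sorted(rng.permutation(n)[:n_a].tolist())
    mask = np.zeros(n, dtype=bool)
    mask[part_a] = True
    ds_a = ds.subset_samples(list(ids[mask]))
    ds_b = ds.subset_samples(list(ids[~mask]))
    for name, part in (("first", ds_a), ("second", ds_b)):
        if part.n_events == 0:
            raise ValueError(f"{name} split part contains zero events; choose another seed or fraction")
    return ds_a, ds_b
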
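"""Binary outcome matrices: reading, validation, and complete-case filtering.

The unit of analysis is a subjects x outcomes table of dichotomous (0/1)
variables, e.g. end-of-program clinical outcomes such as "working",
"living independently", symptomatic remission, or functional recovery.
Outcomes are expected to arrive already dichotomized (instrument cut-offs
such as GAF > 60 are applied upstream); this module only validates and
filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: cell tokens treated as missing by default (clinical CSV dialects vary)
DEFAULT_MISSING_TOKENS = frozenset({"", "NA", "NaN", "."})
DEFAULT_TRUE_TOKENS = frozenset({"1"})
DEFAULT_FALSE_TOKENS = frozenset({"0"})


class DataValidationError(ValueError):
    """Raised when an input table violates the binary-outcome contract."""


@dataclass(frozen=True)
class OutcomeMatrix:
    """Subjects x binary outcomes, with optional missingness and stratum.

    Parameters
    ----------
    subject_ids : list of str
        Unique, opaque subject identifiers (row labels).
    outcome_names : list of str
        Unique outcome labels (column order is meaningful and preserved).
    values : numpy.ndarray of float, shape (n_subjects, n_outcomes)
        Entries are 0.0, 1.0 or NaN (missing).
    strata_name : str, optional
        Label of the stratification variable, if any.
    strata : numpy.ndarray of float, optional
        Per-subject stratum in {0.0, 1.0, NaN}.
    """

    subject_ids: list[str]
    outcome_names: list[str]
    values: np.ndarray
    strata_name: str | None = None
    strata: np.ndarray | None = None

    def __post_init__(self) -> None:
        ids = list(self.subject_ids)
        names = list(self.outcome_names)
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataValidationError(f"duplicate subject id(s): {dupes}")
        if len(set(names)) != len(names) or not names:
            raise DataValidationError("outcome names must be unique and non-empty")
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(ids), len(names)):
            raise DataValidationError(
                f"values shape {vals.shape} does not match "
                f"{len(ids)} subjects x {len(names)} outcomes"
            )
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            r, c = np.argwhere(~ok)[0]
            raise DataValidationError(
                f"non-binary value {vals[r, c]!r} at subject "
                f"{ids[r]!r}, outcome {names[c]!r}"
            )
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "subject_ids", ids)
        object.__setattr__(self, "outcome_names", names)
        if self.strata is not None:
            s = np.asarray(self.strata, dtype=float)
            if s.shape != (len(ids),):
                raise DataValidationError("strata length does not match subjects")
            ok = np.isnan(s) | (s == 0.0) | (s == 1.0)
            if not ok.all():
                r = int(np.argwhere(~ok)[0][0])
                raise DataValidationError(
                    f"non-binary stratum value {s[r]!r} for subject {ids[r]!r}"
                )
            object.__setattr__(self, "strata", s)

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.outcome_names.index(name)
        except ValueError:
            raise KeyError(f"unknown outcome {name!r}") from None
        return self.values[:, j]

    def take(self, row_mask: np.ndarray) -> "OutcomeMatrix":
        """Row subset preserving order, column set and stratum."""
        idx = np.asarray(row_mask)
        return OutcomeMatrix(
            subject_ids=[s for s, k in zip(self.subject_ids, idx) if k],
            outcome_names=self.outcome_names,
            values=self.values[idx],
            strata_name=self.strata_name,
            strata=None if self.strata is None else self.strata[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        """Outcomes (and stratum) as a nullable-integer DataFrame.

        Uses pandas' ``Int64`` dtype so a CSV written from the frame
        round-trips through :func:`read_outcomes` (cells ``0``/``1``,
        missing as empty).
        """
        df = pd.DataFrame(
            self.values, index=pd.Index(self.subject_ids, name="id"),
            columns=self.outcome_names,
        )
        if self.strata is not None:
            df[self.strata_name] = self.strata
        return df.astype("Int64")

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        outcome_columns: list[str] | None = None,
        strata_column: str | None = None,
    ) -> "OutcomeMatrix":
        """Build from a DataFrame (index = subject ids, columns = outcomes)."""
        cols = list(outcome_columns) if outcome_columns is not None else [
            c for c in df.columns if c != strata_column
        ]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise DataValidationError(f"missing outcome column(s): {missing}")
        strata = None
        if strata_column is not None:
            if strata_column not in df.columns:
                raise DataValidationError(f"missing strata column {strata_column!r}")
            strata = df[strata_column].astype("Float64").to_numpy(
                dtype=float, na_value=np.nan)
        return cls(
            subject_ids=[str(i) for i in df.index],
            outcome_names=cols,
            values=df[cols].astype("Float64").to_numpy(dtype=float, na_value=np.nan),
            strata_name=strata_column,
            strata=strata,
        )


@dataclass(frozen=True)
class FilterReport:
    """Accounting of a complete-case filter pass."""

    n_before: int
    n_after: int

    @property
    def n_dropped(self) -> int:
        return self.n_before - self.n_after


def _parse_cell(
    token: str,
    row_id: str,
    column: str,
    missing_tokens: frozenset[str],
    true_tokens: frozenset[str],
    false_tokens: frozenset[str],
) -> float:
    t = token.strip()
    if t in missing_tokens:
        return np.nan
    if t in true_tokens:
        return 1.0
    if t in false_tokens:
        return 0.0
    raise DataValidationError(
        f"unparseable cell {token!r} at row {row_id!r}, column {column!r}: "
        "expected 0, 1 or a missing token"
    )


def read_outcomes(
    path,
    id_column: str,
    outcome_columns: list[str],
    strata_column: str | None = None,
    missing_tokens: frozenset[str] = DEFAULT_MISSING_TOKENS,
    true_tokens: frozenset[str] = DEFAULT_TRUE_TOKENS,
    false_tokens: frozenset[str] = DEFAULT_FALSE_TOKENS,
    delimiter: str = ",",
) -> OutcomeMatrix:
    """Read a CSV of binary outcomes into a validated :class:`OutcomeMatrix`.

    The file must have a header row. Cells are parsed from ``true_tokens`` /
    ``false_tokens`` (default ``"1"`` / ``"0"``); tokens in ``missing_tokens``
    become missing values. Anything else raises
    :class:`DataValidationError` naming the offending row, column and token.
    """
    df = pd.read_csv(path, dtype=str, sep=delimiter, keep_default_na=False,
                     comment="#")
    wanted = [id_column, *outcome_columns]
    if strata_column is not None:
        wanted.append(strata_column)
    absent = [c for c in wanted if c not in df.columns]
    if absent:
        raise DataValidationError(
            f"column(s) {absent} not found in header {list(df.columns)}"
        )
    ids = [str(v).strip() for v in df[id_column]]
    parse_cols = outcome_columns + ([strata_column] if strata_column else [])
    parsed = {
        col: np.array([
            _parse_cell(tok, rid, col, missing_tokens, true_tokens, false_tokens)
            for rid, tok in zip(ids, df[col])
        ])
        for col in parse_cols
    }
    values = np.column_stack([parsed[c] for c in outcome_columns])
    return OutcomeMatrix(
        subject_ids=ids,
        outcome_names=list(outcome_columns),
        values=values,
        strata_name=strata_column,
        strata=parsed[strata_column] if strata_column else None,
    )


def complete_case_filter(m: OutcomeMatrix) -> tuple[OutcomeMatrix, FilterReport]:
    """Keep only subjects with no missing value on any outcome.

    This mirrors the usual inclusion rule for implication analyses of
    clinical outcomes: a subject enters the analysis only if every analyzed
    outcome is observed. Stratum missingness does *not* drop a row here;
    stratified analyses subset on the stratum separately.

    Returns the filtered matrix and a :class:`FilterReport`. Raises
    :class:`DataValidationError` if no complete case remains.
    """
    keep = ~np.isnan(m.values).any(axis=1)
    out = m.take(keep)
    report = FilterReport(n_before=m.n, n_after=out.n)
    if out.n == 0:
        raise DataValidationError("no complete cases")
    logger.info(
        "complete-case filter: kept %d of %d subjects (%d dropped)",
        report.n_after, report.n_before, report.n_dropped,
    )
    return out, report
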
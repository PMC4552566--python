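"""Reading, validating and writing tidy longitudinal cohort tables.

The canonical exchange format is a long/tidy CSV with one row per
subject x metabolite x sampling stage and the seven columns

    subject_id, group, metabolite, stage, workload_w, time_min, concentration_um

Stages are ``rest``, one label per workload level (any label; levels are
ordered by ``workload_w``) and ``recovery``.  Missing concentrations are
empty cells — never 0 or a sentinel, since 0 uM would look biologically
meaningful and below-LOD filtering happens upstream of this table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Required columns of the tidy cohort table, in canonical order.
COHORT_COLUMNS = (
    "subject_id",
    "group",
    "metabolite",
    "stage",
    "workload_w",
    "time_min",
    "concentration_um",
)

REST = "rest"
RECOVERY = "recovery"


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class CohortValidationError(ValueError):
    """The table violates a structural invariant (ordering, missing stages)."""


def _stage_sort_key(df: pd.DataFrame) -> pd.Series:
    """Sort key placing rest first, levels by workload, recovery last."""
    key = df["workload_w"].fillna(0.0).astype(float).copy()
    key[df["stage"] == REST] = -np.inf
    key[df["stage"] == RECOVERY] = np.inf
    return key


@dataclass
class Cohort:
    """A validated tidy cohort table plus optional per-subject metadata.

    Parameters
    ----------
    data
        Tidy table with the :data:`COHORT_COLUMNS` columns.  Rows are
        re-sorted into stage order (rest, levels by ascending workload,
        recovery) per subject and metabolite on construction.
    metadata
        Optional per-subject anthropometrics; never required by the
        pipeline.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"cohort table is missing column(s): {', '.join(missing)}")
        df = self.data.loc[:, list(COHORT_COLUMNS)].copy()
        df["subject_id"] = df["subject_id"].astype(str)
        df["metabolite"] = df["metabolite"].astype(str)
        df["stage"] = df["stage"].astype(str)
        for col in ("workload_w", "time_min", "concentration_um"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        # workload order is checked in file order: a table listing levels
        # out of ascending-workload order is corrupt, not merely unsorted
        for (sid, _met), grp in df.groupby(["subject_id", "metabolite"], sort=False):
            w = grp.loc[~grp["stage"].isin([REST, RECOVERY]), "workload_w"].to_numpy(float)
            if (np.diff(w) <= 0).any():
                raise CohortValidationError(
                    f"subject {sid}: workload not strictly increasing across levels"
                )
        df = (
            df.assign(_key=_stage_sort_key(df))
            .sort_values(["subject_id", "metabolite", "_key"], kind="stable")
            .drop(columns="_key")
            .reset_index(drop=True)
        )
        self.data = df
        self._validate()

    def _validate(self) -> None:
        neg = self.data["concentration_um"] < 0
        if neg.any():
            bad = self.data.loc[neg, "subject_id"].iloc[0]
            raise CohortValidationError(f"negative concentration for subject {bad}")
        for (sid, met), grp in self.data.groupby(["subject_id", "metabolite"], sort=False):
            stages = grp["stage"].tolist()
            if stages.count(REST) != 1:
                raise CohortValidationError(
                    f"subject {sid}, metabolite {met}: expected exactly one rest stage"
                )
            if stages.count(RECOVERY) != 1:
                raise CohortValidationError(
                    f"subject {sid}, metabolite {met}: expected exactly one recovery stage"
                )
            if len(set(stages)) != len(stages):
                raise CohortValidationError(
                    f"subject {sid}, metabolite {met}: duplicate stage labels"
                )
            w = grp.loc[~grp["stage"].isin([REST, RECOVERY]), "workload_w"].to_numpy(float)
            if np.isnan(w).any():
                raise CohortValidationError(
                    f"subject {sid}, metabolite {met}: level stage without workload"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.data["subject_id"]))

    @property
    def metabolites(self) -> list[str]:
        return list(dict.fromkeys(self.data["metabolite"]))

    def series(self, subject_id: str, metabolite: str) -> pd.DataFrame:
        """One subject's sampled trajectory for one metabolite, stage-ordered."""
        mask = (self.data["subject_id"] == str(subject_id)) & (
            self.data["metabolite"] == metabolite
        )
        return self.data.loc[mask].reset_index(drop=True)

    def iter_series(self, metabolite: str) -> Iterable[tuple[str, pd.DataFrame]]:
        sub = self.data[self.data["metabolite"] == metabolite]
        for sid, grp in sub.groupby("subject_id", sort=False):
            yield sid, grp.reset_index(drop=True)


def read_cohort(path, metadata_path=None, **read_csv_kwargs) -> Cohort:
    """Read a tidy cohort CSV into a validated :class:`Cohort`.

    Empty concentration cells are preserved as missing values (NaN).
    Raises :class:`SchemaError` for missing columns and
    :class:`CohortValidationError` for structural violations such as a
    non-monotone workload sequence or an absent rest/recovery stage.
    """
    df = pd.read_csv(path, **read_csv_kwargs)
    metadata = pd.read_csv(metadata_path) if metadata_path is not None else None
    return Cohort(df, metadata=metadata)


def write_table(records: pd.DataFrame, path) -> None:
    """Write any tabular result as CSV (UTF-8, header row, '.' decimals).

    Round-trips through :func:`pandas.read_csv` without loss for the
    cohort schema; an empty frame yields a header-only file.
    """
    if records.shape[1] == 0:
        raise ValueError("refusing to write a table with no columns")
    records.to_csv(path, index=False)


def write_cohort(cohort: Cohort, path) -> None:
    write_table(cohort.data, path)


def _stage_matches(rows: pd.DataFrame, stage_spec: str) -> pd.Series:
    """Match rows by stage label, or by workload via the ``'<W>W'`` syntax.

    Stage identity (not workload) is the primary key — recovery has no
    workload — but exclusions recorded as e.g. ``175W`` are resolved
    against ``workload_w`` for convenience.
    """
    spec = str(stage_spec).strip()
    token = spec.removeprefix("level@")
    if token.endswith("W") and token[:-1].replace(".", "", 1).isdigit():
        return rows["workload_w"] == float(token[:-1])
    return rows["stage"] == spec


def apply_exclusions(
    cohort: Cohort,
    exclusions: Sequence[tuple[str, str, str]] | pd.DataFrame,
) -> tuple[Cohort, int]:
    """Blank the concentrations named by a manual exclusion list.

    Each entry is ``(subject_id, stage, metabolite)`` where metabolite
    ``"*"`` means all panel metabolites and stage accepts either a stage
    label or a workload spelled ``175W``/``level@175W``.  Matching cells
    are set to missing; rows are never removed.  Entries referencing an
    unknown subject raise a warning, not an error.

    Returns the new cohort and the number of concentrations blanked.
    """
    if isinstance(exclusions, pd.DataFrame):
        entries = list(
            exclusions[["subject_id", "stage", "metabolite"]].itertuples(index=False, name=None)
        )
    else:
        entries = list(exclusions)
    df = cohort.data.copy()
    n_removed = 0
    known = set(df["subject_id"])
    for subject_id, stage_spec, metabolite in entries:
        subject_id = str(subject_id)
        if subject_id not in known:
            warnings.warn(
                f"exclusion references unknown subject {subject_id!r}; ignored",
                stacklevel=2,
            )
            continue
        mask = (df["subject_id"] == subject_id) & _stage_matches(df, stage_spec)
        if str(metabolite) != "*":
            mask &= df["metabolite"] == str(metabolite)
        n_hit = int((mask & df["concentration_um"].notna()).sum())
        df.loc[mask, "concentration_um"] = np.nan
        n_removed += n_hit
        logger.info(
            "exclusion (%s, %s, %s): blanked %d value(s)", subject_id, stage_spec, metabolite, n_hit
        )
    return Cohort(df, metadata=cohort.metadata), n_removed


def read_exclusions(path) -> pd.DataFrame:
    """Read an exclusion list CSV with columns subject_id, stage, metabolite."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ("subject_id", "stage", "metabolite") if c not in df.columns]
    if missing:
        raise SchemaError(f"exclusion list is missing column(s): {', '.join(missing)}")
    return df


#: Documented manual exclusions of the reference study: all recovery values of
#: subject 14, all 175 W values of subject 35, and the resting glucose value of
#: subject 42, each removed after visual inspection of the raw curves.
STUDY_EXCLUSIONS: tuple[tuple[str, str, str], ...] = (
    ("14", RECOVERY, "*"),
    ("35", "175W", "*"),
    ("42", REST, "Glucose"),
)
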
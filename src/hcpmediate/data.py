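"""Two-level trial data: container, CSV I/O, validation and centering.

The canonical in-memory representation is a :class:`TrialDataset`, a thin
wrapper around a long-format :class:`pandas.DataFrame` with one row per
individual and four analysis columns: ``cluster`` (opaque label),
``treatment`` (0/1, constant within cluster), ``mediator`` and ``outcome``
(continuous).  Derived columns (cluster means, within-cluster deviations)
are appended by the transforms below and kept alongside the raw columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical analysis column names
CLUSTER, TREATMENT, MEDIATOR, OUTCOME = "cluster", "treatment", "mediator", "outcome"
ANALYSIS_COLUMNS = (CLUSTER, TREATMENT, MEDIATOR, OUTCOME)


class ValidationError(ValueError):
    """Input data violate a structural requirement of the two-level design."""


class ConfigError(ValueError):
    """A configuration problem (missing column, bad mapping, bad option)."""


@dataclass(frozen=True)
class ClusterSummary:
    """Per-cluster aggregate: size, arm, and observed means."""

    cluster_id: object
    n: int
    treatment: int
    mediator_mean: float
    outcome_mean: float


@dataclass(frozen=True)
class TrialDataset:
    """Validated long-format data from a two-level cluster-randomised trial.

    Parameters
    ----------
    df
        One row per individual with at least the canonical analysis columns.
    mediator_higher_is_worse
        Direction convention of the mediator scale (default ``True``: e.g.
        a victimisation score where higher means more victimised).
    outcome_higher_is_better
        Direction convention of the outcome scale (default ``True``: e.g.
        a wellbeing score where higher means better wellbeing).
    n_dropped
        Rows removed during validation for missing analysis values.
    treatment_mapping
        If the raw treatment column was not already 0/1, the mapping that
        was applied ({original value: 0 or 1}).
    """

    df: pd.DataFrame
    mediator_higher_is_worse: bool = True
    outcome_higher_is_better: bool = True
    n_dropped: int = 0
    treatment_mapping: dict | None = field(default=None)

    # -- construction ----------------------------------------------------

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        *,
        mediator_higher_is_worse: bool = True,
        outcome_higher_is_better: bool = True,
    ) -> "TrialDataset":
        """Validate a raw frame and return a dataset.

        Performs listwise deletion on the analysis columns (logged),
        recodes a two-valued treatment column to 0/1 if needed, and checks
        the design invariants: treatment constant within cluster and at
        least two clusters per arm.
        """
        missing = [c for c in ANALYSIS_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigError(f"missing required column(s): {missing}")

        df = df.copy()
        n_before = len(df)
        df[MEDIATOR] = pd.to_numeric(df[MEDIATOR], errors="coerce")
        df[OUTCOME] = pd.to_numeric(df[OUTCOME], errors="coerce")
        keep = (
            df[MEDIATOR].notna()
            & df[OUTCOME].notna()
            & np.isfinite(df[MEDIATOR])
            & np.isfinite(df[OUTCOME])
            & df[TREATMENT].notna()
            & df[CLUSTER].notna()
        )
        df = df.loc[keep].reset_index(drop=True)
        n_dropped = n_before - len(df)
        if n_dropped:
            logger.warning(
                "dropped %d of %d rows with missing analysis variables",
                n_dropped,
                n_before,
            )
        if df.empty:
            raise ValidationError("no complete rows remain after listwise deletion")

        df, mapping = _recode_treatment(df)

        per_cluster = df.groupby(CLUSTER, sort=False)[TREATMENT].nunique()
        bad = per_cluster[per_cluster > 1]
        if len(bad):
            raise ValidationError(
                "treatment varies within cluster(s) "
                f"{list(bad.index)}; allocation must be at cluster level"
            )
        arm_counts = df.groupby(CLUSTER, sort=False)[TREATMENT].first().value_counts()
        for arm in (0, 1):
            if arm_counts.get(arm, 0) < 2:
                raise ValidationError(
                    f"need at least 2 clusters in arm {arm}, "
                    f"found {arm_counts.get(arm, 0)}"
                )
        return cls(
            df=df,
            mediator_higher_is_worse=mediator_higher_is_worse,
            outcome_higher_is_better=outcome_higher_is_better,
            n_dropped=n_dropped,
            treatment_mapping=mapping,
        )

    # -- convenience -----------------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def n_clusters(self) -> int:
        return self.df[CLUSTER].nunique()

    def cluster_ids(self) -> list:
        return list(self.df[CLUSTER].drop_duplicates())

    def with_columns(self, **cols) -> "TrialDataset":
        """Return a copy with extra/overwritten columns."""
        return replace(self, df=self.df.assign(**cols))


def _recode_treatment(df: pd.DataFrame) -> tuple[pd.DataFrame, dict | None]:
    values = pd.unique(df[TREATMENT])
    if len(values) != 2:
        raise ValidationError(
            f"treatment must take exactly 2 values, found {sorted(map(str, values))}"
        )
    as_set = set(values.tolist())
    if as_set == {0, 1}:
        df[TREATMENT] = df[TREATMENT].astype(int)
        return df, None
    # explicit, logged recode: lexicographically smaller value -> control
    lo, hi = sorted(values, key=str)
    mapping = {lo: 0, hi: 1}
    logger.warning("recoding treatment column with mapping %r", mapping)
    df[TREATMENT] = df[TREATMENT].map(mapping).astype(int)
    return df, mapping


# -- I/O ------------------------------------------------------------------


def read_trial_csv(
    path,
    columns: dict[str, str] | None = None,
    *,
    mediator_higher_is_worse: bool = True,
    outcome_higher_is_better: bool = True,
) -> TrialDataset:
    """Read a long-format trial CSV and return a validated dataset.

    ``columns`` maps canonical names (``cluster``, ``treatment``,
    ``mediator``, ``outcome``) to the column names in the file; canonical
    names absent from the map are assumed to appear verbatim.
    """
    raw = pd.read_csv(path, float_precision="round_trip")
    columns = columns or {}
    rename = {}
    for canonical in ANALYSIS_COLUMNS:
        source = columns.get(canonical, canonical)
        if source not in raw.columns:
            raise ConfigError(
                f"column {source!r} (for {canonical!r}) not found in {path}; "
                f"available: {list(raw.columns)}"
            )
        rename[source] = canonical
    raw = raw.rename(columns=rename)
    return TrialDataset.from_frame(
        raw[list(ANALYSIS_COLUMNS)],
        mediator_higher_is_worse=mediator_higher_is_worse,
        outcome_higher_is_better=outcome_higher_is_better,
    )


def write_trial_csv(data: TrialDataset, path, *, include_derived: bool = False) -> None:
    """Write the dataset back to CSV (optionally with derived columns)."""
    cols = list(ANALYSIS_COLUMNS)
    if include_derived:
        cols += [c for c in data.df.columns if c not in cols]
    data.df[cols].to_csv(path, index=False)


# -- summaries and centering ----------------------------------------------


def cluster_summaries(data: TrialDataset) -> list[ClusterSummary]:
    """One summary (size, arm, mediator/outcome means) per cluster."""
    g = data.df.groupby(CLUSTER, sort=False)
    agg = g.agg(
        n=(MEDIATOR, "size"),
        treatment=(TREATMENT, "first"),
        mediator_mean=(MEDIATOR, "mean"),
        outcome_mean=(OUTCOME, "mean"),
    )
    return [
        ClusterSummary(
            cluster_id=cid,
            n=int(row.n),
            treatment=int(row.treatment),
            mediator_mean=float(row.mediator_mean),
            outcome_mean=float(row.outcome_mean),
        )
        for cid, row in agg.iterrows()
    ]


def add_cluster_means(data: TrialDataset, variable: str = MEDIATOR) -> TrialDataset:
    """Append the observed cluster mean of ``variable`` as a column.

    The mean is the manifest (observed) mean of retained records — the
    quantity a between-level regression on cluster means uses.
    """
    means = data.df.groupby(CLUSTER, sort=False)[variable].transform("mean")
    return data.with_columns(**{f"{variable}_cluster_mean": means})


def center_within_cluster(data: TrialDataset, variable: str = MEDIATOR) -> TrialDataset:
    """Append the within-cluster deviation ``x_ij - mean_j(x)``.

    Within every cluster the deviations sum to zero by construction; a
    single-member cluster gets deviation 0.  Also appends the cluster-mean
    column if not already present.
    """
    out = add_cluster_means(data, variable)
    dev = out.df[variable] - out.df[f"{variable}_cluster_mean"]
    return out.with_columns(**{f"{variable}_dev": dev})
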
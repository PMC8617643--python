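"""Tabular containers shared across the pipeline.

The central object is :class:`MetaboliteTable`, a thin wrapper around a
samples x features :class:`pandas.DataFrame` that tracks how far along the
preprocessing chain the values are (``raw`` peak areas through ``scaled``
model-ready data).  Sample metadata (treatment, day after sowing, replicate)
travels separately as a plain DataFrame indexed by sample id.
"""

from __future__ import annotations

import pandas as pd

#: canonical order of processing states
STATES = (
    "raw",
    "is_normalized",
    "median_normalized",
    "filtered",
    "log2",
    "imputed",
    "scaled",
)

METADATA_COLUMNS = ("treatment", "das", "replicate")

TREATMENTS = ("minusAM", "plusAM")


class MetaboliteTable:
    """Samples x features matrix with a processing-state flag.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with one column per feature id.
        ``NaN`` encodes a missing (undetected) value.
    state
        One of :data:`STATES`.
    """

    def __init__(self, values: pd.DataFrame, state: str = "raw"):
        if state not in STATES:
            raise ValueError(f"unknown state {state!r}; expected one of {STATES}")
        self.values = values.astype(float)
        self.state = state

    # -- convenience -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "MetaboliteTable":
        return MetaboliteTable(self.values.copy(), self.state)

    def with_values(self, values: pd.DataFrame, state: str | None = None) -> "MetaboliteTable":
        return MetaboliteTable(values, state if state is not None else self.state)

    def require_state(self, *allowed: str) -> None:
        if self.state not in allowed:
            raise ValueError(
                f"operation requires table state in {allowed}, got {self.state!r}"
            )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, j = self.values.shape
        return f"<MetaboliteTable {n} samples x {j} features, state={self.state!r}>"


def validate_metadata(metadata: pd.DataFrame) -> None:
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    bad = set(metadata["treatment"]) - set(TREATMENTS)
    if bad:
        raise ValueError(f"unknown treatments {sorted(bad)}; expected {TREATMENTS}")


def replicate_groups(metadata: pd.DataFrame):
    """Yield ``((treatment, das), sample_id_list)`` replicate groups."""
    validate_metadata(metadata)
    for key, sub in metadata.groupby(["treatment", "das"], sort=True):
        yield key, list(sub.index)


def write_table_tsv(table: MetaboliteTable, metadata: pd.DataFrame, path) -> None:
    """Write the matrix TSV dialect: sample_id/treatment/das/replicate, then features."""
    out = metadata.loc[table.sample_ids, list(METADATA_COLUMNS)].join(table.values)
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_table_tsv(path, state: str = "raw") -> tuple[MetaboliteTable, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    meta = df[list(METADATA_COLUMNS)].copy()
    values = df.drop(columns=list(METADATA_COLUMNS))
    validate_metadata(meta)
    return MetaboliteTable(values, state), meta
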
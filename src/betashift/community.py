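"""Community-table data model, CSV I/O and the square-root transform.

A community table holds non-negative quantities (biomass in g·m⁻², or any
abundance-like measure) for a set of observations (site × time × replicate
transects) over a set of species, together with aligned per-observation
metadata.  Raw biomass data are typically right-skewed, so analyses are
usually run on square-root transformed values, which places the replacement /
abundance-difference decomposition between a raw-biomass and a
presence-absence analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CommunityTable",
    "ValidationError",
    "AlignmentError",
    "read_community",
    "write_community",
    "apply_transform",
]

#: metadata columns required for every observation
META_REQUIRED = ("site", "time", "replicate")
#: optional metadata columns carried through when present
META_OPTIONAL = ("season", "coral_cover")

TRANSFORMS = ("identity", "sqrt")


class ValidationError(ValueError):
    """A community table or metadata table violates an invariant."""


class AlignmentError(ValueError):
    """Community and metadata tables do not describe the same observations."""


@dataclass
class CommunityTable:
    """Observations × species quantities with aligned observation metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative quantities, indexed by observation id, one column per
        species.  Column order is preserved.
    meta : pandas.DataFrame
        Per-observation metadata indexed identically to ``values``.  Must
        contain ``site`` (categorical), ``time`` (real-valued axis, e.g.
        calendar year with wet-season surveys at ``year + 0.0`` and
        dry-season surveys at ``year + 0.5``) and ``replicate``; may contain
        ``season`` ({"wet", "dry"}) and ``coral_cover`` (percent, [0, 100]).
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    transform: str = field(default="identity")

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------ api
    @property
    def obs_ids(self) -> pd.Index:
        return self.values.index

    @property
    def species_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_species(self) -> int:
        return self.values.shape[1]

    def matrix(self) -> np.ndarray:
        """Return the quantity matrix as a float ndarray (observations × species)."""
        return self.values.to_numpy(dtype=float)

    def copy(self) -> "CommunityTable":
        return CommunityTable(self.values.copy(), self.meta.copy(), self.transform)

    # ------------------------------------------------------------- checking
    def validate(self) -> None:
        """Raise :class:`ValidationError` / :class:`AlignmentError` on any
        violated invariant (duplicated ids, negative cells, missing data,
        misaligned metadata, non-unique (site, time, replicate))."""
        v, m = self.values, self.meta
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated observation id(s): {dup}")
        if v.isna().any().any():
            cell = next(zip(*np.nonzero(v.isna().to_numpy())))
            raise ValidationError(
                f"missing value at observation {v.index[cell[0]]!r}, "
                f"species {v.columns[cell[1]]!r}"
            )
        arr = v.to_numpy(dtype=float)
        if (arr < 0).any():
            i, j = next(zip(*np.nonzero(arr < 0)))
            raise ValidationError(
                f"negative quantity {arr[i, j]} at observation "
                f"{v.index[i]!r}, species {v.columns[j]!r}"
            )
        missing_cols = [c for c in META_REQUIRED if c not in m.columns]
        if missing_cols:
            raise ValidationError(f"metadata lacks required column(s): {missing_cols}")
        if not v.index.equals(m.index):
            only_v = v.index.difference(m.index).tolist()
            only_m = m.index.difference(v.index).tolist()
            raise AlignmentError(
                f"community/metadata ids differ (community-only: {only_v[:5]}, "
                f"metadata-only: {only_m[:5]})"
            )
        if not np.issubdtype(np.asarray(m["time"]).dtype, np.number):
            raise ValidationError("metadata 'time' must be numeric")
        design = m[list(META_REQUIRED)]
        if design.duplicated().any():
            dup = design[design.duplicated()].iloc[0].tolist()
            raise ValidationError(f"duplicated (site, time, replicate) combination: {dup}")
        if "coral_cover" in m.columns:
            cc = m["coral_cover"].dropna().to_numpy(dtype=float)
            if ((cc < 0) | (cc > 100)).any():
                raise ValidationError("coral_cover must lie in [0, 100]")
        if self.transform not in TRANSFORMS:
            raise ValidationError(f"unknown transform {self.transform!r}")


def _sorted(values: pd.DataFrame, meta: pd.DataFrame):
    order = meta.sort_values(["site", "time", "replicate"], kind="stable").index
    return values.loc[order], meta.loc[order]


def read_community(community_path, meta_path) -> CommunityTable:
    """Read a community table and its metadata from two CSV files.

    The community CSV is wide: first column the observation id, remaining
    columns one species each.  The metadata CSV is keyed by the same
    observation id with columns ``site, year (or time), season, replicate,
    coral_cover``.  Rows are normalized to (site, time, replicate) order;
    species keep file order.
    """
    values = pd.read_csv(community_path, index_col=0)
    meta = pd.read_csv(meta_path, index_col=0)
    if "time" not in meta.columns and "year" in meta.columns:
        meta = meta.rename(columns={"year": "time"})
    try:
        table = CommunityTable(*_sorted(values, meta))
    except KeyError as exc:  # sort on missing required column
        raise ValidationError(f"metadata lacks required column: {exc}") from exc
    return table


def write_community(table: CommunityTable, community_path, meta_path) -> None:
    """Write the two CSVs in the dialect :func:`read_community` expects."""
    table.values.rename_axis("obs_id").to_csv(community_path)
    table.meta.rename_axis("obs_id").to_csv(meta_path)


def apply_transform(table: CommunityTable, transform: str = "sqrt") -> CommunityTable:
    """Return a new table with ``transform`` applied elementwise to the values.

    ``"sqrt"`` compresses large quantities and reduces asymmetry (zeros map
    to zeros); ``"identity"`` is a no-op.  Metadata are untouched.
    """
    if transform not in TRANSFORMS:
        raise ValidationError(f"unknown transform {transform!r}")
    if transform == "identity":
        return table.copy()
    values = pd.DataFrame(
        np.sqrt(table.values.to_numpy(dtype=float)),
        index=table.values.index,
        columns=table.values.columns,
    )
    return CommunityTable(values, table.meta.copy(), transform="sqrt")
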
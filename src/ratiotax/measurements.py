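"""Specimen-by-variable tables of positive linear measurements.

A :class:`MeasurementTable` is the common input container for the
morphometric analyses in this package: rows are specimens, columns are
strictly positive lengths (mm), and every specimen carries a categorical
group label (a population or a putative species).  Two standard variable
sets from land-snail taxonomy are provided as module constants: seven
shell dimensions and six distal-genitalia dimensions.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

#: Shell variables: aperture height/width, adapical and medial last-whorl
#: heights, shell diameter, shell height, umbilicus diameter.
SHELL_VARIABLES: tuple[str, ...] = ("AH", "AW", "LWaH", "LWmH", "SD", "SH", "UD")

#: Distal-genitalia variables: bursa copulatrix duct, epiphallus, flagellum,
#: penis, vagina, vaginal appendix.
GENITAL_VARIABLES: tuple[str, ...] = ("DBC", "E", "F", "P", "V", "VA")


class MeasurementTable:
    """Specimens x positive measurements with group labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric measurements, indexed by specimen identifier, one column
        per variable.  All cells must be present and strictly positive.
    groups : pandas.Series
        Group label per specimen, indexed like ``values``.
    """

    def __init__(self, values: pd.DataFrame, groups: pd.Series):
        values = values.copy()
        if values.shape[1] < 2:
            raise ValueError("a measurement table needs at least 2 variables")
        if not values.index.is_unique:
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicate specimen_id {dup!r}")
        try:
            values = values.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric measurement: {exc}") from exc
        if values.isna().any().any():
            sid, var = next(
                (s, v) for s in values.index for v in values.columns
                if pd.isna(values.at[s, v])
            )
            raise ValueError(f"missing measurement for specimen {sid!r}, variable {var!r}")
        if (values <= 0).any().any():
            sid, var = next(
                (s, v) for s in values.index for v in values.columns
                if values.at[s, v] <= 0
            )
            raise ValueError(
                f"non-positive measurement {values.at[sid, var]!r} "
                f"for specimen {sid!r}, variable {var!r}"
            )
        groups = pd.Series(groups).reindex(values.index)
        if groups.isna().any():
            sid = groups.index[groups.isna()][0]
            raise ValueError(f"missing group label for specimen {sid!r}")
        values.index.name = "specimen_id"
        self.values = values
        self.groups = groups.astype(str)
        self.groups.index.name = "specimen_id"

    # -- constructors -------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        id_col: str = "specimen_id",
        group_col: str = "group",
        variables: Sequence[str] | None = None,
    ) -> "MeasurementTable":
        """Build from a long table holding id and group columns."""
        frame = frame.copy()
        if id_col in frame.columns:
            frame = frame.set_index(id_col)
        groups = frame.pop(group_col)
        if variables is not None:
            frame = frame.loc[:, list(variables)]
        return cls(frame, groups)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "MeasurementTable":
        """Read ``specimen_id,group,<var1>,...`` CSV (decimal point, UTF-8)."""
        return cls.from_dataframe(pd.read_csv(path), **kwargs)

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "group", self.groups)
        out.to_csv(path, index_label="specimen_id")

    # -- views ---------------------------------------------------------

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    @property
    def specimen_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_specimens(self) -> int:
        return len(self.values)

    def group_sizes(self) -> pd.Series:
        return self.groups.value_counts()

    def log_values(self) -> pd.DataFrame:
        """Natural-log measurements (the scale all MRA machinery works on)."""
        return np.log(self.values)

    def subset(self, groups: Iterable[str]) -> "MeasurementTable":
        """Restrict to specimens belonging to the given groups."""
        wanted = set(groups)
        unknown = wanted - set(self.groups)
        if unknown:
            raise KeyError(f"unknown group(s): {sorted(unknown)}")
        keep = self.groups.isin(wanted)
        return MeasurementTable(self.values.loc[keep], self.groups.loc[keep])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MeasurementTable {self.n_specimens} specimens x "
            f"{len(self.variables)} variables, groups={sorted(set(self.groups))}>"
        )
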
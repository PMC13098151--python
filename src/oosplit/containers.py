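"""In-memory containers for half-oocyte proteome matrices and twin-pair tables.

Both containers wrap :class:`pandas.DataFrame` objects and validate the
structural invariants the downstream analyses rely on (two halves per
oocyte, two members per pair, non-negative counts).  Absent measurements
are represented as ``NaN`` and are distinct from zeros throughout.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EQUATORIAL = "equatorial"
MERIDIONAL = "meridional"
AXES = (EQUATORIAL, MERIDIONAL)

#: hemisphere labels per bisection axis: equatorial separates animal (A)
#: from vegetal (V); meridional separates the spindle side (R) from the
#: other (L), an arbitrary but consistent convention.
HEMISPHERES = {EQUATORIAL: ("A", "V"), MERIDIONAL: ("L", "R")}

ICSI_GROUPS = ("ipsilateral", "equatorial", "contralateral", "NF")

LINEAGES = ("epiblast", "primitive_endoderm", "trophectoderm")


class InvalidInputError(ValueError):
    """Raised when an input table violates a structural invariant."""


class HalfProteomeMatrix:
    """Protein abundances for the two hemispheres of ``N`` bisected oocytes.

    Parameters
    ----------
    values : DataFrame
        Protein x half abundance matrix.  Rows are protein identifiers,
        columns are half identifiers.  ``NaN`` marks a protein that was
        not detected in that half (absent, not zero).
    design : DataFrame
        One row per half (index = half identifier) with columns
        ``oocyte`` (oocyte of origin) and ``hemisphere`` (one of
        ``A``/``V`` for equatorial bisections, ``L``/``R`` for
        meridional ones).
    axis : str
        ``"equatorial"`` or ``"meridional"``.
    """

    def __init__(self, values: pd.DataFrame, design: pd.DataFrame, axis: str):
        if axis not in AXES:
            raise InvalidInputError(f"axis must be one of {AXES}, got {axis!r}")
        values = values.copy()
        design = design.copy()
        if values.index.duplicated().any():
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise InvalidInputError(f"duplicate protein identifiers: {dupes}")
        if values.columns.duplicated().any():
            dupes = values.columns[values.columns.duplicated()].unique().tolist()
            raise InvalidInputError(f"duplicate half identifiers: {dupes}")
        missing_cols = {"oocyte", "hemisphere"} - set(design.columns)
        if missing_cols:
            raise InvalidInputError(f"design table lacks columns {sorted(missing_cols)}")
        if set(values.columns) != set(design.index):
            raise InvalidInputError(
                "matrix columns and design half identifiers do not match"
            )
        design = design.loc[values.columns]
        allowed = set(HEMISPHERES[axis])
        seen = set(design["hemisphere"])
        if not seen <= allowed:
            raise InvalidInputError(
                f"hemisphere labels {sorted(seen - allowed)} invalid for {axis} axis"
            )
        for oocyte, sub in design.groupby("oocyte"):
            if len(sub) != 2:
                raise InvalidInputError(
                    f"oocyte {oocyte!r} has {len(sub)} halves; exactly 2 required"
                )
            if sub["hemisphere"].iloc[0] == sub["hemisphere"].iloc[1]:
                raise InvalidInputError(
                    f"oocyte {oocyte!r} has two {sub['hemisphere'].iloc[0]!r} halves"
                )
        values = values.astype(float)
        values.index.name = "protein_id"
        values.columns.name = None
        design.index.name = "half_id"
        self.values = values
        self.design = design
        self.axis = axis

    # ------------------------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def half_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_oocytes(self) -> int:
        return self.design["oocyte"].nunique()

    @property
    def oocyte_of(self) -> pd.Series:
        return self.design["oocyte"]

    @property
    def hemisphere_of(self) -> pd.Series:
        return self.design["hemisphere"]

    def subset(self, protein_ids: Iterable[str]) -> "HalfProteomeMatrix":
        """Return the submatrix restricted to ``protein_ids`` (order kept)."""
        ids = pd.Index(protein_ids)
        unknown = ids.difference(self.values.index)
        if len(unknown):
            raise InvalidInputError(f"unknown protein identifiers: {unknown.tolist()}")
        return HalfProteomeMatrix(self.values.loc[ids], self.design, self.axis)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"HalfProteomeMatrix({self.n_proteins} proteins x "
            f"{len(self.half_ids)} halves, axis={self.axis!r})"
        )


class TwinPairTable:
    """Paired per-blastocyst measurements keyed by pair and ICSI-site group.

    ``data`` holds one row per blastocyst with columns ``pair_id``,
    ``sample_id``, ``group``, ``total_cells`` and the three lineage
    counts; ``es_colonies`` and ``actb_tpm`` are optional.  An optional
    gene x sample TPM matrix may accompany the table.  The a/b ordering
    ("twin a" = lower key value) is added by
    :func:`oosplit.twins.assign_ab` as a ``role`` column.
    """

    REQUIRED = ("pair_id", "sample_id", "group")
    COUNT_COLUMNS = ("total_cells",) + LINEAGES + ("es_colonies",)

    def __init__(self, data: pd.DataFrame, tpm: pd.DataFrame | None = None):
        data = data.copy().reset_index(drop=True)
        missing = set(self.REQUIRED) - set(data.columns)
        if missing:
            raise InvalidInputError(f"pair table lacks columns {sorted(missing)}")
        if data["sample_id"].duplicated().any():
            dupes = data.loc[data["sample_id"].duplicated(), "sample_id"].tolist()
            raise InvalidInputError(f"duplicate sample identifiers: {dupes}")
        sizes = data.groupby("pair_id").size()
        bad = sizes[sizes != 2]
        if len(bad):
            raise InvalidInputError(
                f"pairs must have exactly 2 members; offending pairs: "
                f"{bad.index.tolist()}"
            )
        for col in self.COUNT_COLUMNS:
            if col in data.columns:
                vals = pd.to_numeric(data[col], errors="coerce")
                if (vals.dropna() < 0).any():
                    raise InvalidInputError(f"negative values in column {col!r}")
                data[col] = vals
        if all(c in data.columns for c in ("total_cells",) + LINEAGES):
            lineage_sum = data[list(LINEAGES)].sum(axis=1, skipna=False)
            over = lineage_sum > data["total_cells"]
            if over.fillna(False).any():
                rows = data.loc[over.fillna(False), "sample_id"].tolist()
                raise InvalidInputError(
                    f"lineage counts exceed total cells for samples {rows}"
                )
        if tpm is not None:
            tpm = tpm.copy()
            if tpm.index.duplicated().any():
                dupes = tpm.index[tpm.index.duplicated()].unique().tolist()
                raise InvalidInputError(f"duplicate gene identifiers: {dupes}")
            extra = set(tpm.columns) - set(data["sample_id"])
            if extra:
                raise InvalidInputError(
                    f"TPM matrix has samples absent from the pair table: {sorted(extra)}"
                )
            if (tpm.fillna(0) < 0).any().any():
                raise InvalidInputError("TPM values must be non-negative")
        self.data = data
        self.tpm = tpm

    # ------------------------------------------------------------------
    @property
    def pair_ids(self) -> Sequence:
        return self.data["pair_id"].unique()

    @property
    def groups(self) -> Sequence:
        return self.data["group"].unique()

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    def with_data(self, data: pd.DataFrame) -> "TwinPairTable":
        """Rebuild the table around a replacement ``data`` frame."""
        tpm = None
        if self.tpm is not None:
            keep = [c for c in self.tpm.columns if c in set(data["sample_id"])]
            tpm = self.tpm[keep]
        return TwinPairTable(data, tpm)

    def members(self, pair_id) -> pd.DataFrame:
        sub = self.data[self.data["pair_id"] == pair_id]
        if sub.empty:
            raise KeyError(pair_id)
        return sub

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        ngene = 0 if self.tpm is None else self.tpm.shape[0]
        return f"TwinPairTable({self.n_pairs} pairs, {ngene} genes)"
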
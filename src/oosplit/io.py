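"""TSV readers and writers for every table the package consumes or emits.

All tabular I/O is UTF-8 TSV with a header row; missing values are
written as ``NA`` and read back as absent (never as zero).  Every writer
has a matching reader so any output of the package can be re-read by the
package.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import HalfProteomeMatrix, InvalidInputError, TwinPairTable

NA_REP = "NA"

PAIR_COLUMNS = [
    "pair_id", "sample_id", "group", "total_cells", "epiblast",
    "primitive_endoderm", "trophectoderm", "es_colonies", "actb_tpm", "role",
]


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return pd.read_csv(path, sep="\t", na_values=[NA_REP],
                           keep_default_na=False, **kwargs)
    except Exception as exc:  # pragma: no cover - context only
        raise InvalidInputError(f"failed to parse {path}: {exc}") from exc


def _write_tsv(frame: pd.DataFrame, path, index: bool) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", na_rep=NA_REP, index=index)


# ----------------------------------------------------------------------
# half-proteome matrices
# ----------------------------------------------------------------------

def write_proteome(matrix: HalfProteomeMatrix, matrix_path, design_path) -> None:
    _write_tsv(matrix.values.rename_axis("protein_id"), matrix_path, index=True)
    design = matrix.design.rename_axis("half_id").copy()
    design["axis"] = matrix.axis
    _write_tsv(design, design_path, index=True)


def read_proteome(matrix_path, design_path) -> HalfProteomeMatrix:
    values = _read_tsv(matrix_path, index_col="protein_id")
    design = _read_tsv(design_path, index_col="half_id")
    if "axis" not in design.columns:
        raise InvalidInputError(f"{design_path}: design table lacks 'axis' column")
    axes = design["axis"].unique()
    if len(axes) != 1:
        raise InvalidInputError(f"{design_path}: mixed axes {axes.tolist()}")
    return HalfProteomeMatrix(values, design.drop(columns="axis"), str(axes[0]))


# ----------------------------------------------------------------------
# twin-pair tables and TPM matrices
# ----------------------------------------------------------------------

def write_pair_table(table: TwinPairTable, path, tpm_path=None) -> None:
    cols = [c for c in PAIR_COLUMNS if c in table.data.columns]
    extra = [c for c in table.data.columns if c not in cols]
    _write_tsv(table.data[cols + extra], path, index=False)
    if tpm_path is not None:
        if table.tpm is None:
            raise InvalidInputError("pair table has no TPM matrix to write")
        write_tpm(table.tpm, tpm_path)


def read_pair_table(path, tpm_path=None) -> TwinPairTable:
    data = _read_tsv(path)
    tpm = read_tpm(tpm_path) if tpm_path is not None else None
    return TwinPairTable(data, tpm)


def write_tpm(tpm: pd.DataFrame, path) -> None:
    _write_tsv(tpm.rename_axis("gene"), path, index=True)


def read_tpm(path) -> pd.DataFrame:
    tpm = _read_tsv(path, index_col="gene")
    if tpm.index.duplicated().any():
        dupes = tpm.index[tpm.index.duplicated()].unique().tolist()
        raise InvalidInputError(f"{path}: duplicate gene identifiers {dupes}")
    return tpm


# ----------------------------------------------------------------------
# geometry tables
# ----------------------------------------------------------------------

def write_angles(records: pd.DataFrame, path) -> None:
    _write_tsv(records[["zygote_id", "icsi_site", "angle_deg"]], path,
               index=False)


def read_angles(path) -> pd.DataFrame:
    records = _read_tsv(path)
    missing = {"zygote_id", "icsi_site", "angle_deg"} - set(records.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    if records["zygote_id"].duplicated().any():
        raise InvalidInputError(f"{path}: duplicate zygote identifiers")
    return records


def write_circumferences(pairs: pd.DataFrame, path) -> None:
    _write_tsv(pairs[["id", "c1_um", "c2_um"]], path, index=False)


def read_circumferences(path) -> pd.DataFrame:
    pairs = _read_tsv(path)
    missing = {"id", "c1_um", "c2_um"} - set(pairs.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    if (pairs[["c1_um", "c2_um"]] <= 0).any().any():
        raise InvalidInputError(f"{path}: circumferences must be positive")
    return pairs
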
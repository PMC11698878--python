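"""CSV schemas and readers/writers for the pipeline's tables.

One dialect only: comma-separated, '.' decimal, UTF-8, header required.
Round-tripping any table through write-then-read is the identity.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import pandas as pd

from .cohort import ScoreRecord
from .learning_curve import LearningCurveFit
from .staircase import BlockSeries

__all__ = [
    "SCHEMAS",
    "read_table",
    "write_table",
    "trials_frame",
    "blocks_frame",
    "scores_frame",
    "params_frame",
    "read_trials",
    "read_blocks",
    "read_scores",
    "read_params",
]

# column name -> pandas dtype, per table
SCHEMAS: dict[str, dict[str, str]] = {
    "trials": {
        "subject": "string", "block": "int64", "trial": "int64",
        "level": "float64", "correct": "bool", "stepped": "string",
        "reversal": "bool",
    },
    "blocks": {
        "subject": "string", "block": "int64", "threshold": "float64",
        "n_trials": "int64", "n_reversals": "int64", "accuracy": "float64",
        "valid": "bool",
    },
    "scores": {
        "subject": "string", "group": "string", "age": "float64",
        "sex": "string", "education": "string", "occupation": "string",
        "moca_pre": "int64", "moca_post": "int64", "moca_gain": "int64",
        "mmse_pre": "int64", "mmse_post": "int64", "mmse_gain": "int64",
    },
    "params": {
        "subject": "string", "alpha": "float64", "beta": "float64",
        "gamma": "float64", "initial": "float64", "r_squared": "float64",
        "converged": "bool",
    },
}

_DECIMAL_COMMA = re.compile(r"^-?\d+,\d+$")


class CsvFormatError(ValueError):
    pass


def write_table(df: pd.DataFrame, path, schema: str) -> Path:
    cols = list(SCHEMAS[schema])
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{schema} table is missing columns: {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df[cols].to_csv(path, index=False, encoding="utf-8")
    return path


def read_table(path, schema: str) -> pd.DataFrame:
    """Read one of the documented CSV schemas with strict validation.

    Raises a named error for empty input, reports the line number of a
    malformed row, rejects decimal-comma numerics with a format hint,
    and warns on unknown columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise CsvFormatError(f"empty input: {path}")
    spec = SCHEMAS[schema]
    raw = pd.read_csv(path, dtype="string", encoding="utf-8", keep_default_na=False)
    if raw.empty and raw.columns.size == 0:
        raise CsvFormatError(f"empty input: {path}")
    unknown = [c for c in raw.columns if c not in spec]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown column(s) {unknown}", stacklevel=2)
    missing = [c for c in spec if c not in raw.columns]
    if missing:
        raise CsvFormatError(f"{path}: missing required column(s) {missing}")

    out = {}
    for col, dtype in spec.items():
        series = raw[col]
        if dtype in ("float64", "int64"):
            commas = series.str.match(_DECIMAL_COMMA, na=False)
            if commas.any():
                line = int(commas.idxmax()) + 2  # +1 header, +1 one-based
                raise CsvFormatError(
                    f"{path}, line {line}: decimal comma in column {col!r}; "
                    "this reader expects '.' as the decimal separator"
                )
            converted = pd.to_numeric(series, errors="coerce")
            bad = converted.isna() & (series != "")
            if bad.any():
                line = int(bad.idxmax()) + 2
                raise CsvFormatError(
                    f"{path}, line {line}: malformed value {series[bad.idxmax()]!r} "
                    f"in column {col!r}"
                )
            out[col] = converted.astype(dtype)
        elif dtype == "bool":
            lowered = series.str.lower()
            ok = lowered.isin(["true", "false"])
            if not ok.all():
                line = int((~ok).idxmax()) + 2
                raise CsvFormatError(
                    f"{path}, line {line}: malformed boolean {series[(~ok).idxmax()]!r} "
                    f"in column {col!r}"
                )
            out[col] = lowered == "true"
        else:
            out[col] = series.astype("string")
    return pd.DataFrame(out)


def trials_frame(series_list: list[BlockSeries]) -> pd.DataFrame:
    rows = []
    for series in series_list:
        for block in series.blocks:
            for t in block.trials:
                rows.append(
                    (series.subject_id, block.block_index, t.trial_index,
                     t.level, t.correct, t.stepped, t.is_reversal)
                )
    return pd.DataFrame(rows, columns=list(SCHEMAS["trials"]))


def blocks_frame(series_list: list[BlockSeries]) -> pd.DataFrame:
    rows = []
    for series in series_list:
        for b in series.blocks:
            rows.append(
                (series.subject_id, b.block_index,
                 float("nan") if b.threshold_estimate is None else b.threshold_estimate,
                 b.n_trials, b.n_reversals, b.accuracy, b.valid)
            )
    return pd.DataFrame(rows, columns=list(SCHEMAS["blocks"]))


def scores_frame(records: list[ScoreRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.subject_id, r.group, r.age, r.sex, r.education, r.occupation,
             r.moca_pre, r.moca_post, r.moca_gain,
             r.mmse_pre, r.mmse_post, r.mmse_gain)
            for r in records
        ],
        columns=list(SCHEMAS["scores"]),
    )


def params_frame(fits: list[LearningCurveFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (f.subject_id, f.alpha, f.beta, f.gamma, f.initial_performance,
             f.r_squared, f.converged)
            for f in fits
        ],
        columns=list(SCHEMAS["params"]),
    )


def read_trials(path) -> pd.DataFrame:
    return read_table(path, "trials")


def read_blocks(path) -> pd.DataFrame:
    return read_table(path, "blocks")


def read_scores(path) -> pd.DataFrame:
    return read_table(path, "scores")


def read_params(path) -> pd.DataFrame:
    return read_table(path, "params")
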
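"""Delimited-text round trips for choice data and survey records.

Choice data travel as one row per respondent x task x alternative.  Two
layouts are accepted: pre-coded (the coded design columns present) and raw
(one column per attribute holding verbatim level labels, coded here against a
design config).  Validation failures name the offending rows or labels.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .choice_models import ChoiceDataset, ID_COLUMNS
from .experimental_design import OPT_OUT_COLUMN, AttributeSpec, design_columns, effects_code

__all__ = [
    "write_choice_data",
    "load_choice_data",
    "write_survey",
    "load_survey",
    "recode_money_continuous",
]


class ChoiceDataValidationError(ValueError):
    pass


def write_choice_data(dataset: ChoiceDataset, path: str | Path, sep: str = ",") -> None:
    cols = ID_COLUMNS + [c for c in dataset.columns if c not in ID_COLUMNS]
    extra = [c for c in dataset.df.columns if c not in cols]
    dataset.df[cols + extra].to_csv(path, sep=sep, index=False)


def load_choice_data(
    path: str | Path,
    attributes: list[AttributeSpec] | None = None,
    sep: str = ",",
) -> ChoiceDataset:
    """Read a choice-data file, coding raw level labels when needed.

    With ``attributes`` given and coded columns absent, each attribute column
    must hold verbatim level labels (or short level codes); opt-out rows are
    those with ``opt_out == 1`` (their label cells may be blank).
    """
    df = pd.read_csv(path, sep=sep)
    missing_ids = set(ID_COLUMNS) - set(df.columns)
    if missing_ids:
        raise ChoiceDataValidationError(f"missing required columns: {sorted(missing_ids)}")

    if attributes is not None:
        coded_cols = design_columns(attributes)
        if not set(coded_cols) <= set(df.columns):
            df = _code_raw_labels(df, attributes)
        return _validated(df, coded_cols)

    id_like = set(ID_COLUMNS)
    coded_cols = [c for c in df.columns if c not in id_like]
    return _validated(df, coded_cols)


def _code_raw_labels(df: pd.DataFrame, attributes: list[AttributeSpec]) -> pd.DataFrame:
    if OPT_OUT_COLUMN not in df.columns:
        raise ChoiceDataValidationError("raw-label files must carry an opt_out column")
    missing_attrs = [a.name for a in attributes if a.name not in df.columns]
    if missing_attrs:
        raise ChoiceDataValidationError(f"missing attribute label columns: {missing_attrs}")

    coded_cols = design_columns(attributes)
    n_attr_cols = len(coded_cols) - 1
    coded = np.zeros((len(df), n_attr_cols))
    is_profile = df[OPT_OUT_COLUMN].to_numpy() != 1
    level_maps = []
    for attr in attributes:
        m = {lv: i for i, lv in enumerate(attr.levels)}
        m.update({c: i for i, c in enumerate(attr.level_codes)})
        level_maps.append(m)
    for pos in np.where(is_profile)[0]:
        profile = []
        for attr, m in zip(attributes, level_maps):
            label = df.iloc[pos][attr.name]
            if label not in m:
                raise ChoiceDataValidationError(
                    f"unknown level label {label!r} for attribute {attr.name!r} (row {pos})"
                )
            profile.append(m[label])
        coded[pos] = effects_code(profile, attributes)
    out = df[ID_COLUMNS + [OPT_OUT_COLUMN]].copy()
    for j, c in enumerate(coded_cols[:-1]):
        out[c] = coded[:, j]
    return out


def _validated(df: pd.DataFrame, coded_cols: list[str]) -> ChoiceDataset:
    grp = df.groupby(["respondent_id", "task_id"], sort=False)["chosen"].sum()
    bad = grp[grp != 1]
    if len(bad):
        raise ChoiceDataValidationError(
            f"tasks without exactly one chosen alternative: {bad.index.tolist()[:10]}"
        )
    try:
        return ChoiceDataset(df=df, columns=coded_cols)
    except ValueError as err:
        raise ChoiceDataValidationError(str(err)) from err


def write_survey(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)


def load_survey(path: str | Path, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)


def recode_money_continuous(
    dataset: ChoiceDataset,
    attributes: list[AttributeSpec],
    money_name: str = "money",
    scale: float = 1000.0,
) -> ChoiceDataset:
    """Replace the effects-coded money columns by one continuous column.

    The new ``money`` column holds the level's GMD amount divided by ``scale``
    (default: thousands of GMD, for optimiser conditioning; the scale is
    recorded in the dataset metadata so money coefficients can be reported
    back per GMD).  Opt-out rows keep money 0.
    """
    money_attr = next((a for a in attributes if a.name == money_name), None)
    if money_attr is None:
        raise ValueError(f"no attribute named {money_name!r}")
    if money_attr.numeric_values is None:
        raise ValueError(f"attribute {money_name!r} has no numeric level values")
    money_cols = money_attr.column_names()
    if not set(money_cols) <= set(dataset.columns):
        raise ValueError("dataset does not carry the effects-coded money columns")

    codes = np.eye(money_attr.n_levels - 1).tolist() + [[-1.0] * (money_attr.n_levels - 1)]
    M = dataset.df[money_cols].to_numpy(float)
    values = np.zeros(len(M))
    is_profile = dataset.df[OPT_OUT_COLUMN].to_numpy() != 1
    for pos in np.where(is_profile)[0]:
        row = M[pos]
        for lvl, pattern in enumerate(codes):
            if np.allclose(row, pattern):
                values[pos] = money_attr.numeric_values[lvl] / scale
                break
        else:
            raise ValueError(f"row {pos}: money columns do not match any level coding")

    df = dataset.df.drop(columns=money_cols).copy()
    new_cols = []
    for c in dataset.columns:
        if c == money_cols[0]:
            new_cols.append(money_name)
        elif c in money_cols:
            continue
        else:
            new_cols.append(c)
    df[money_name] = values
    return ChoiceDataset(
        df=df,
        columns=new_cols,
        metadata={**dataset.metadata, "money_scale": scale},
    )
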
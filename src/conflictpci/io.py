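"""CSV reading/writing for survey and region tables (RFC 4180, UTF-8)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .config import GeneratorConfig

SURVEY_KEY_COLUMNS = ["respondent_id", "municipality_id", "sex", "age", "education"]
REGION_KEY_COLUMNS = [
    "municipality_id",
    "county_id",
    "country",
    "human_density",
    "big_game_tradition",
    "sheep_density",
    "wolf_zone",
]


class SchemaError(ValueError):
    pass


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\r\n", encoding="utf-8")


def _check_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def read_survey(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = SURVEY_KEY_COLUMNS + [f"item_{i}" for i in range(1, 17)]
    _check_columns(df, required, path)
    items = df[[f"item_{i}" for i in range(1, 17)]]
    bad = ~(items.isna() | items.isin([1, 2, 3, 4, 5]))
    if bad.any().any():
        col = bad.any()[bad.any()].index[0]
        row = int(bad[col].idxmax())
        raise SchemaError(f"{path}: row {row} column {col} is not a Likert 1-5 value")
    return df


def read_regions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, REGION_KEY_COLUMNS, path)
    if df["municipality_id"].duplicated().any():
        dup = df["municipality_id"][df["municipality_id"].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicated municipality_id {dup!r}")
    return df


def write_config_echo(config: GeneratorConfig, seed: int, path) -> None:
    """Flat key = value echo of the generator configuration (documented sidecar)."""
    lines = [f"master_seed = {seed}"]
    for key, value in sorted(config.to_dict().items()):
        lines.append(f"{key} = {value!r}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
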
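"""Reading and validating subject-level tables (CSV or XLSX)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

REQUIRED_COLUMNS = (
    "id",
    "sex",
    "age_years",
    "ses_score",
    "screen_hours",
    "sleep_min",
    "sb_min",
    "lpa_min",
    "mvpa_min",
    "zbmi",
)

BEHAVIOR_COLUMNS = ("sleep_min", "sb_min", "lpa_min", "mvpa_min")


class SchemaError(ValueError):
    pass


# alias sets for externally deposited spreadsheets whose headers differ
# from the canonical schema; matched on lowercased, stripped names
_ALIASES: dict[str, tuple[str, ...]] = {
    "sleep_min": ("sleep", "sleep_min", "sono", "tst", "sleep (min)", "sleep_minutes"),
    "sb_min": ("sb", "sb_min", "sedentary", "sb (min)"),
    "lpa_min": ("lpa", "lpa_min", "lpa (min)"),
    "mvpa_min": ("mvpa", "mvpa_min", "mvpa (min)"),
    "zbmi": ("zbmi", "bmi_z", "zimc", "bmi z-score", "z_bmi", "bmiz"),
    "age_years": ("age", "age_years", "idade", "age (years)"),
    "sex": ("sex", "sexo", "gender"),
    "ses_score": ("ses", "ses_score", "nse", "socioeconomic", "abep"),
    "screen_hours": ("st", "screen", "screen_hours", "screen_time", "st_hours", "tt"),
    "id": ("id", "subject", "participant", "code"),
}


def load_external_table(path: str | Path) -> pd.DataFrame:
    """Best-effort loader for a deposited subject spreadsheet.

    Normalizes headers through a documented alias list, synthesizes an
    ``id`` column when absent, then applies the standard validation with
    the behavior/outcome columns required.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path)
    rename: dict[str, str] = {}
    for col in raw.columns:
        key = str(col).strip().lower()
        for canon, aliases in _ALIASES.items():
            if key == canon or key in aliases:
                rename[col] = canon
                break
    table = raw.rename(columns=rename)
    if "id" not in table.columns:
        table["id"] = [f"s{i + 1:04d}" for i in range(len(table))]
    required = ("sleep_min", "sb_min", "lpa_min", "mvpa_min", "zbmi", "age_years")
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: could not map columns for {missing}; "
            f"available: {list(raw.columns)}"
        )
    for col in BEHAVIOR_COLUMNS + ("zbmi", "age_years"):
        table[col] = pd.to_numeric(table[col], errors="coerce")
    return table


def read_subject_table(
    path: str | Path,
    rename: dict[str, str] | None = None,
    required: tuple[str, ...] = REQUIRED_COLUMNS,
) -> pd.DataFrame:
    """Load and validate a subject table from CSV or XLSX.

    ``rename`` maps source column names onto the canonical schema
    (useful for externally deposited spreadsheets).  Validation errors
    carry 1-based data row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        table = pd.read_excel(path)
    else:
        table = pd.read_csv(path)
    if rename:
        table = table.rename(columns=rename)
    table.columns = [str(c).strip().lower() for c in table.columns]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    errors: list[str] = []
    for col in BEHAVIOR_COLUMNS:
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[~(vals > 0)].tolist()
        for i in bad:
            errors.append(f"row {i + 1}, column {col}: non-positive or missing value")
        table[col] = vals
    for col in ("age_years", "zbmi", "ses_score", "screen_hours"):
        if col in table.columns:
            table[col] = pd.to_numeric(table[col], errors="coerce")
    if errors:
        raise SchemaError(f"{path.name}: " + "; ".join(errors))
    return table.reset_index(drop=True)
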
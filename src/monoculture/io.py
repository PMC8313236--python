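"""Delimited-text I/O for effect-size tables and run manifests.

All tables are UTF-8 CSV with a header row; missing values are empty
fields.  The effect-size schema is defined here and validated on read.
"""

from __future__ import annotations

import json
import platform
import sys
from datetime import datetime, timezone

import numpy as np
import pandas as pd

__all__ = [
    "EFFECT_COLUMNS",
    "MODERATOR_COLUMNS",
    "read_effect_table",
    "write_effect_table",
    "write_run_manifest",
]

#: moderator columns carried by every effect-size record
MODERATOR_COLUMNS = (
    "pathogen_presence",        # present | absent
    "measure",                  # mortality | pathogen_abundance
    "pathogen_manipulated",     # experimental | observational
    "relatedness_manipulated",  # experimental | observational
    "kin_structure",            # kin | non_kin
    "setting",                  # lab | field
    "inbreeding_possible",      # true | false
    "analysis_technique",       # free label
)

#: full effect-size table schema, in column order
EFFECT_COLUMNS = (
    "study_id",
    "species_id",
    "effect_type",          # Zr | LnCVR
    "value",
    "sampling_variance",
    "n_groups",
) + MODERATOR_COLUMNS

_CATEGORICAL_LEVELS = {
    "effect_type": {"Zr", "LnCVR"},
    "pathogen_presence": {"present", "absent"},
    "measure": {"mortality", "pathogen_abundance"},
    "pathogen_manipulated": {"experimental", "observational"},
    "relatedness_manipulated": {"experimental", "observational"},
    "kin_structure": {"kin", "non_kin"},
    "setting": {"lab", "field"},
}


def read_effect_table(path, validate: bool = True) -> pd.DataFrame:
    """Read an effect-size table (CSV) and validate its schema.

    Checks required columns, positive sampling variances, the
    four-group minimum, and categorical levels; raises ``ValueError``
    naming the problem.  Records with an intermediate relatedness
    treatment (``relatedness_level == 'intermediate'``, if such a
    column is present) are dropped at ingestion — only low-vs-high
    comparisons are retained.
    """
    df = pd.read_csv(path)
    if "relatedness_level" in df.columns:
        df = df[df["relatedness_level"] != "intermediate"].copy()
    if validate:
        validate_effect_table(df)
    return df


def validate_effect_table(df: pd.DataFrame) -> None:
    missing = [c for c in EFFECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"effect table missing columns: {missing}")
    if (df["sampling_variance"] <= 0).any():
        raise ValueError("sampling_variance must be strictly positive")
    if (df["n_groups"] < 4).any():
        raise ValueError("records require four or more groups")
    if not np.isfinite(df["value"].to_numpy(dtype=float)).all():
        raise ValueError("effect values must be finite")
    for col, levels in _CATEGORICAL_LEVELS.items():
        bad = set(df[col].dropna().unique()) - levels
        if bad:
            raise ValueError(f"column {col!r} has unknown levels: {sorted(bad)}")


def write_effect_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in EFFECT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False)


def write_run_manifest(path, *, seed, config: dict | None = None) -> None:
    """Record the seed, configuration and versions of a run as JSON."""
    from . import __version__

    manifest = {
        "package": "monoculture",
        "version": __version__,
        "seed": seed,
        "config": config or {},
        "python": sys.version.split()[0],
        "platform": platform.platform(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
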
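"""Adapter for a local copy of the TAME Pain corpus layout.

The adapter expects ``root/metadata.csv`` with at least the columns below
(extra columns such as quality ratings are passed through), and maps them
onto the internal corpus schema.  Clips without a pain label are dropped.
It validates loudly against the expected schema rather than guessing
alternative layouts.

Expected columns
----------------
file            relative WAV path
participant     speaker identifier
pain_label      'pain' / 'non-pain' (empty = unlabelled, dropped)
intensity       'mild' / 'moderate' / 'severe' (empty for non-pain)
condition       'cold' / 'warm'
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["EXPECTED_COLUMNS", "tame_adapter"]

EXPECTED_COLUMNS = ("file", "participant", "pain_label", "intensity", "condition")


def tame_adapter(root: str | Path, quality_max: int | None = None) -> pd.DataFrame:
    """Map a TAME-layout directory to the internal corpus table.

    ``quality_max``: optionally keep only clips whose ``quality`` column is
    <= the given value (0 = clean); by default no quality filter is applied.
    """
    root = Path(root)
    meta = root / "metadata.csv"
    if not meta.exists():
        raise FileNotFoundError(f"no metadata.csv under {root}")
    raw = pd.read_csv(meta)
    missing = [c for c in EXPECTED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(
            f"schema mismatch in {meta}: missing columns {missing}; "
            f"expected at least {list(EXPECTED_COLUMNS)}"
        )
    labelled = raw[raw["pain_label"].notna() & (raw["pain_label"] != "")].copy()
    if quality_max is not None:
        if "quality" not in labelled.columns:
            raise ValueError("quality filter requested but no 'quality' column present")
        labelled = labelled[labelled["quality"] <= quality_max]
    if len(labelled) == 0:
        raise ValueError(f"no labelled clips found under {root}")
    intensity = labelled["intensity"].fillna("none").replace("", "none")
    table = pd.DataFrame(
        {
            "clip_id": [Path(f).stem for f in labelled["file"]],
            "speaker_id": labelled["participant"].astype(str).to_numpy(),
            "pain": labelled["pain_label"].to_numpy(),
            "intensity": intensity.to_numpy(),
            "thermal": labelled["condition"].to_numpy(),
            "duration": labelled["duration"].to_numpy()
            if "duration" in labelled.columns
            else float("nan"),
            "path": labelled["file"].to_numpy(),
        }
    )
    for extra in ("quality", "pain_rating"):
        if extra in labelled.columns:
            table[extra] = labelled[extra].to_numpy()
    table.attrs["root"] = str(root)
    return table
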
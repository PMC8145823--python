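"""Deployment metadata for the captive and free-ranging kingfish trials.

The bundled table carries per-fish tagging context (setting, site, size,
local sunrise/sunset, logger recording hours).  Sunrise/sunset feed the diel
binning of predicted events; recording hours document the ground-truth
budget.  Sun times come from a lookup service for the tagging site — the
package never computes them from coordinates.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_deployments() -> pd.DataFrame:
    """Per-fish deployment metadata (captive C1–C6, free-ranging FR1–FR8)."""
    with resources.files("accelethogram.data").joinpath("deployments.csv").open() as fh:
        return pd.read_csv(fh, dtype={"sunrise": "string", "sunset": "string"})


def captive_recording_hours() -> float:
    """Total captive logger recording time (h) across the six tagged fish."""
    df = load_deployments()
    return float(df.loc[df["setting"] == "captive", "recording_hours"].sum())


def sun_times(fish_id: str) -> tuple[str, str]:
    """(sunrise, sunset) local clock strings for one deployment."""
    df = load_deployments().set_index("fish_id")
    row = df.loc[fish_id]
    if pd.isna(row["sunrise"]) or pd.isna(row["sunset"]):
        raise KeyError(f"no sun times recorded for {fish_id}")
    return str(row["sunrise"]), str(row["sunset"])
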
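"""Packaged reference tables from the published validation study."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_duration_by_species",
    "load_branch_precision",
    "load_published_comparison",
    "demo_scenario_path",
]


def _load(name: str) -> pd.DataFrame:
    with resources.files("hcnmeter.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_duration_by_species() -> pd.DataFrame:
    """Per-species weighted-mean HCN release durations (minutes): mean, SD, range, n."""
    return _load("duration_by_species.csv")


def load_branch_precision() -> pd.DataFrame:
    """Quartic-trend precision summaries for leaves along branches (RMSE, range, %error)."""
    return _load("branch_precision.csv")


def load_published_comparison() -> pd.DataFrame:
    """Species means: published dry-weight HCN vs calibrated cup measurements."""
    return _load("published_comparison.csv")


def demo_scenario_path() -> str:
    """Filesystem path of the packaged demo scenario YAML."""
    return str(resources.files("hcnmeter.data").joinpath("demo_scenario.yaml"))
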
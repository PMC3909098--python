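"""Run configuration and sample metadata.

``RunConfig`` collects every tunable threshold of the pipeline in one
place; ``SampleSheet`` maps samples to condition groups and to their
junction-count tables. Both can be loaded from YAML/TSV so that a run is
fully described by its config, seed, and inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import pandas as pd
import yaml

__all__ = ["RunConfig", "SampleSheet", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Thresholds governing event building, PSI, and differential calls.

    Parameters
    ----------
    min_event_count
        Minimum pooled read count required of every junction in an event
        (reads; events with any weaker junction are discarded).
    psi_min_total
        Minimum inclusion+exclusion read support for a PSI value to be
        defined in a sample (reads).
    delta_thresh
        Minimum |median ΔPSI| (percent) for an event to be *tested* in
        the group comparison.
    median_delta_filter
        Minimum |median ΔPSI| (percent) for a tested event to be called
        significant after FDR control.
    fdr_alpha
        Benjamini–Hochberg significance level (fraction).
    jcn_seq_len
        Effective junction-read length (nt); used only to length-normalise
        intron-body counts for intron-retention PSI.
    switch_dpsi
        Minimum |ΔPSI| (percent) for calling a splice-site switch between
        two conditions.
    continuity
        Whether the normal-approximation rank-sum test applies a
        continuity correction.
    seed
        Seed for any stochastic step.
    """

    min_event_count: float = 2.0
    psi_min_total: int = 10
    delta_thresh: float = 5.0
    median_delta_filter: float = 10.0
    fdr_alpha: float = 0.05
    jcn_seq_len: int = 88
    switch_dpsi: float = 5.0
    continuity: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_event_count", "psi_min_total", "delta_thresh",
                     "median_delta_filter", "jcn_seq_len", "switch_dpsi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not (0.0 < self.fdr_alpha <= 1.0):
            raise ValueError(f"fdr_alpha must be in (0, 1], got {self.fdr_alpha}")

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in fields(RunConfig)}
        unknown = set(loaded) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)


@dataclass
class SampleSheet:
    """Assignment of samples to condition groups.

    ``table`` has columns ``sample_id``, ``group`` and optionally
    ``file_path`` (that sample's junction table). Sample ids must be
    unique, every group non-empty, and file paths distinct.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"sample_id", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {sorted(set(dups))}")
        if (self.table.groupby("group").size() < 1).any() or self.table.empty:
            raise ValueError("every group needs at least one sample")
        if "file_path" in self.table.columns:
            paths = self.table["file_path"].dropna()
            if paths.duplicated().any():
                raise ValueError("sample file paths must be distinct")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    def samples_in(self, group: str) -> list[str]:
        if group not in set(self.table["group"]):
            raise KeyError(f"group {group!r} not present in sample sheet")
        return list(self.table.loc[self.table["group"] == group, "sample_id"])
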
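"""In-memory containers shared by the quantification stages.

The central object is :class:`AbundanceMatrix` — a feature x channel table
with an explicit scale flag (linear vs log2) and an append-only record of the
normalization steps applied, so the fixed pipeline order can be enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .io import PlexDesign, condition_label

__all__ = [
    "AbundanceMatrix",
    "SiteAbundanceMatrix",
    "LipidAbundanceMatrix",
    "OccupancyTable",
    "channel_table",
]

QUANTITATIVE_CLASSES = ("sample", "bridge", "total_thiol_pool")


def channel_table(designs: list[PlexDesign], classes: Iterable[str] = QUANTITATIVE_CLASSES) -> pd.DataFrame:
    """Channel metadata for all quantitative channels of the given plexes,
    indexed by (plex_id, channel_label)."""
    parts = []
    for d in designs:
        block = d.channels(classes).copy()
        block["plex_id"] = d.plex_id
        block["condition"] = [
            condition_label(n, t) for n, t in zip(block["nitrogen"], block["timepoint_h"])
        ]
        parts.append(block)
    meta = pd.concat(parts, ignore_index=True)
    meta.index = pd.MultiIndex.from_frame(meta[["plex_id", "channel_label"]])
    return meta.drop(columns=["plex_id", "channel_label"])


@dataclass
class AbundanceMatrix:
    """Features x channels intensity matrix.

    Parameters
    ----------
    data : DataFrame
        Rows are features, columns are a (plex_id, channel_label) MultiIndex.
        Missing observations are NaN, never zero.
    channels : DataFrame
        Channel metadata aligned with ``data.columns`` (sample_id, nitrogen,
        timepoint_h, replicate, channel_class, batch, condition).
    scale : {"linear", "log2"}
    applied_steps : list of str
        Append-only provenance; re-applying a step is an error.
    """

    data: pd.DataFrame
    channels: pd.DataFrame
    scale: str = "linear"
    feature_kind: str = "feature"
    applied_steps: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.data.columns.equals(self.channels.index):
            raise ValueError("data columns and channel metadata are misaligned")
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")

    # -- provenance -------------------------------------------------------
    def record_step(self, name: str) -> None:
        if name in self.applied_steps:
            raise ValueError(f"step {name!r} already applied (pipeline order violation)")
        self.applied_steps.append(name)

    def _clone(self, data: pd.DataFrame, **kw) -> "AbundanceMatrix":
        out = self.__class__(**{**self.__dict__, "data": data, "applied_steps": list(self.applied_steps), **kw})
        return out

    # -- selections -------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    def columns_where(self, **criteria) -> pd.MultiIndex:
        """Channel columns whose metadata match all criteria
        (e.g. ``condition="low_24h"`` or ``channel_class="sample"``)."""
        mask = pd.Series(True, index=self.channels.index)
        for key, val in criteria.items():
            col = self.channels[key]
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= col.isin(tuple(val))
            else:
                mask &= col == val
        return self.channels.index[mask]

    def condition_columns(self, condition: str) -> pd.MultiIndex:
        """Biological channels (sample or bridge) belonging to a condition."""
        mask = (self.channels["condition"] == condition) & self.channels["channel_class"].isin(
            ("sample", "bridge")
        )
        return self.channels.index[mask]

    @property
    def conditions(self) -> list[str]:
        vals = self.channels["condition"].dropna().unique().tolist()
        order = {"high": 0, "low": 1}
        return sorted(vals, key=lambda c: (int(c.split("_")[1][:-1]), order[c.split("_")[0]]))

    @property
    def plexes(self) -> list[str]:
        return list(self.channels.index.get_level_values(0).unique())

    def subset_features(self, ids: Iterable[str]) -> "AbundanceMatrix":
        return self._clone(self.data.loc[list(ids)])


@dataclass
class SiteAbundanceMatrix(AbundanceMatrix):
    """AbundanceMatrix specialized to PTM site features.

    ``adjusted_for_protein`` flips to True only through
    :func:`ptmflux.ptm_quant.subtract_protein_abundance`; ``orphan_sites``
    records sites left unadjusted because their parent protein was not
    quantified.
    """

    ptm_kind: str = "redox"
    adjusted_for_protein: bool = False
    orphan_sites: list[str] = field(default_factory=list)

    def __post_init__(self):
        super().__post_init__()
        if self.ptm_kind not in ("redox", "phospho"):
            raise ValueError(f"unknown ptm_kind {self.ptm_kind!r}")


@dataclass
class LipidAbundanceMatrix(AbundanceMatrix):
    """AbundanceMatrix specialized to lipid species, keeping class/subclass
    annotation and an immutable record of originally-missing cells."""

    class_map: pd.Series = None
    subclass_map: pd.Series = None
    missing_mask: pd.DataFrame = None

    def __post_init__(self):
        super().__post_init__()
        if self.missing_mask is not None:
            # stored as a defensive copy; set once at load and never rewritten
            self.missing_mask = self.missing_mask.copy()


@dataclass
class OccupancyTable:
    """Per-site, per-condition mean % thiol oxidation.

    Values above 100% can occur under measurement noise; they are retained
    and flagged rather than clipped so distribution summaries stay honest.
    """

    rows: pd.DataFrame  # columns: site, condition, mean_percent_oxidation, over_100

    def __post_init__(self):
        dup = self.rows.duplicated(subset=["site", "condition"])
        if dup.any():
            raise ValueError("OccupancyTable must have one row per (site, condition)")

    def pivot(self) -> pd.DataFrame:
        return self.rows.pivot(index="site", columns="condition", values="mean_percent_oxidation")

    def group_means(self) -> pd.Series:
        """Population mean % oxidation per condition group."""
        return self.rows.groupby("condition")["mean_percent_oxidation"].mean()
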
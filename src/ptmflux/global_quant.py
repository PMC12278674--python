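"""Global protein abundance quantification from PSM-level reporter intensities.

Pipeline order is fixed: rollup -> log2 -> bridge batch correction -> median
centering.  Each step records itself in ``applied_steps``; re-running a step
raises.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, channel_table
from .io import PlexDesign, PSMTable

__all__ = [
    "rollup_protein",
    "rollup_peptide",
    "log2_transform",
    "bridge_batch_correct",
    "median_center_channels",
]

log = logging.getLogger(__name__)


def _rollup(psm: PSMTable, designs: list[PlexDesign], key_col: str, feature_kind: str) -> AbundanceMatrix:
    meta = channel_table(designs)
    blocks = []
    for d in designs:
        rows = psm.rows[psm.rows["plex_id"] == d.plex_id]
        labels = [lab for _, lab in meta.index[meta.index.get_level_values(0) == d.plex_id]]
        present = [lab for lab in labels if lab in rows.columns]
        # sum over a feature's peptides; missing intensities are skipped, and
        # a feature is absent in a channel only when all its peptides are
        block = rows.groupby(key_col)[present].sum(min_count=1)
        block.columns = pd.MultiIndex.from_product([[d.plex_id], block.columns])
        blocks.append(block)
    data = pd.concat(blocks, axis=1)
    data = data.reindex(columns=meta.index)
    data = data[~data.isna().all(axis=1)]
    return AbundanceMatrix(
        data=data, channels=meta, scale="linear", feature_kind=feature_kind,
        applied_steps=[f"rollup_{feature_kind}"],
    )


def rollup_protein(psm: PSMTable, designs: list[PlexDesign]) -> AbundanceMatrix:
    """Sum raw reporter intensities of a protein's (FDR-passing) peptides per
    channel.  Proteins with no quantified peptide in any channel never appear."""
    return _rollup(psm, designs, "protein_id", "protein")


def rollup_peptide(psm: PSMTable, designs: list[PlexDesign]) -> AbundanceMatrix:
    """Peptide-level rollup of the global data (summing a peptide's PSMs);
    this un-batch-corrected matrix anchors TMT channel-loading estimation."""
    return _rollup(psm, designs, "peptide", "peptide")


def log2_transform(m: AbundanceMatrix) -> AbundanceMatrix:
    """Elementwise log2.  Zeros become missing (count logged); negative
    values are an upstream error."""
    if m.scale != "linear":
        raise ValueError("log2_transform expects a linear-scale matrix")
    vals = m.data.to_numpy(dtype=float)
    if np.nanmin(vals, initial=np.inf) < 0:
        raise ValueError("negative intensities cannot be log-transformed")
    n_zero = int((vals == 0).sum())
    if n_zero:
        log.warning("log2_transform: %d zero intensities set to missing", n_zero)
    with np.errstate(divide="ignore"):
        out = np.where(vals > 0, np.log2(np.where(vals > 0, vals, 1.0)), np.nan)
    res = m._clone(pd.DataFrame(out, index=m.data.index, columns=m.data.columns), scale="log2")
    res.record_step("log2")
    return res


def bridge_batch_correct(m: AbundanceMatrix, designs: list[PlexDesign] | None = None) -> AbundanceMatrix:
    """Align plexes feature-wise on the shared bridge channels (24 h
    technical replicates present in every plex).

    For each feature and plex, the offset is the plex's bridge-channel mean
    minus the across-plex bridge mean; it is subtracted from all of that
    plex's channels.  Features unseen in a plex's bridges fall back to the
    plex's median offset over features.  Only whole plex-rows shift, so
    within-plex channel differences are untouched.
    """
    if m.scale != "log2":
        raise ValueError("bridge_batch_correct expects log2 data")
    bridge_cols = m.columns_where(channel_class="bridge")
    if len(bridge_cols) == 0:
        raise ValueError(
            "no bridge channels in any plex; rerun with the per-plex median "
            "fallback (median_center_channels aligns plexes only globally)"
        )
    plexes = m.plexes
    bridge = m.data[bridge_cols]
    per_plex_mean = bridge.T.groupby(level=0).mean().T  # feature x plex
    grand_mean = bridge.mean(axis=1)
    offsets = per_plex_mean.sub(grand_mean, axis=0)
    missing_plexes = sorted(set(plexes) - set(offsets.columns))
    if missing_plexes:
        raise ValueError(f"plexes without any bridge channel: {missing_plexes}")
    # fallback for features without bridge observations in a plex
    fallback = offsets.median(axis=0)
    offsets = offsets.fillna(fallback)
    corrected = m.data.copy()
    for p in plexes:
        cols = corrected.columns[corrected.columns.get_level_values(0) == p]
        corrected[cols] = corrected[cols].sub(offsets[p], axis=0)
    res = m._clone(corrected)
    res.record_step("bridge_batch_correct")
    return res


def median_center_channels(m: AbundanceMatrix) -> AbundanceMatrix:
    """Channel-to-channel median centering: subtract each channel's median
    over its observed features, so every channel median is 0 afterwards."""
    if m.scale != "log2":
        raise ValueError("median_center_channels expects log2 data")
    counts = m.data.notna().sum(axis=0)
    empty = [c for c, n in counts.items() if n < 1]
    if empty:
        raise ValueError(f"channels with no observed features: {empty}")
    centered = m.data.sub(m.data.median(axis=0), axis=1)
    res = m._clone(centered)
    res.record_step("median_center")
    return res
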
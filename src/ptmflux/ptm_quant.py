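"""Site-level PTM quantification: redox (cysteine thiol oxidation) and
phosphoproteomics.

The normalization chain is fixed as

    aggregate -> log2 -> channel-loading scale -> median-center
              -> bridge batch-correct -> per-condition protein subtraction

with thiol-oxidation % occupancy computed on the *linear*, loading-scaled
intensities before the log2 branch (oxidized-channel mean over pooled
total-thiol mean, x100, per condition).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, OccupancyTable, SiteAbundanceMatrix, channel_table
from .global_quant import bridge_batch_correct, log2_transform, median_center_channels
from .io import PlexDesign, PSMTable, parse_site_key

__all__ = [
    "aggregate_sites",
    "channel_loading_offsets",
    "apply_loading_scaling",
    "apply_loading_scaling_linear",
    "subtract_protein_abundance",
    "compute_occupancy",
    "normalize_site_matrix",
]

log = logging.getLogger(__name__)


def aggregate_sites(psm: PSMTable, designs: list[PlexDesign], ptm_kind: str) -> SiteAbundanceMatrix:
    """Sum reporter intensities over the peptides carrying each site key.

    A composite (ambiguous-localization) key such as ``P_S512;T513`` is a
    feature of its own: it aggregates only peptides with the identical
    composite and is never merged into ``P_S512``.  Peptides lacking site
    keys in a PTM table are skipped with a warning.
    """
    meta = channel_table(designs)
    rows = psm.rows
    no_key = ~rows["site_keys"].astype(bool)
    if no_key.any():
        log.warning("aggregate_sites: skipping %d peptides without site keys", int(no_key.sum()))
        rows = rows[~no_key]
    exploded = rows.assign(site=rows["site_keys"].str.split("|")).explode("site")
    blocks = []
    for d in designs:
        sub = exploded[exploded["plex_id"] == d.plex_id]
        labels = [lab for _, lab in meta.index[meta.index.get_level_values(0) == d.plex_id]]
        present = [lab for lab in labels if lab in sub.columns]
        block = sub.groupby("site")[present].sum(min_count=1)
        block.columns = pd.MultiIndex.from_product([[d.plex_id], block.columns])
        blocks.append(block)
    data = pd.concat(blocks, axis=1).reindex(columns=meta.index)
    data = data[~data.isna().all(axis=1)]
    return SiteAbundanceMatrix(
        data=data, channels=meta, scale="linear", feature_kind="site",
        applied_steps=["aggregate_sites"], ptm_kind=ptm_kind,
    )


def channel_loading_offsets(global_peptides: AbundanceMatrix) -> pd.Series:
    """Per-channel loading offsets from the log2 global *peptide* data
    (pre batch correction).

    offset(channel) = median over peptides in that channel minus the grand
    median of the per-channel medians.  Returned as a Series indexed by
    (batch, channel_label) so the same physical TMT channel can be matched
    across the assay-specific plexes.
    """
    if global_peptides.scale != "log2":
        raise ValueError("channel_loading_offsets expects log2 peptide data")
    if "bridge_batch_correct" in global_peptides.applied_steps:
        raise ValueError("loading offsets must come from un-batch-corrected data")
    med = global_peptides.data.median(axis=0)
    if med.isna().any():
        bad = list(med.index[med.isna()])
        raise ValueError(f"channels absent from the global peptide data: {bad}")
    offsets = med - med.median()
    offsets.index = pd.MultiIndex.from_arrays(
        [global_peptides.channels["batch"].to_numpy(),
         global_peptides.channels.index.get_level_values(1)],
        names=["batch", "channel_label"],
    )
    return offsets


def _match_offsets(m: AbundanceMatrix, offsets: pd.Series) -> np.ndarray:
    keys = list(zip(m.channels["batch"], m.channels.index.get_level_values(1)))
    missing = [k for k in keys if k not in offsets.index]
    if missing:
        raise ValueError(f"no loading offset for channels {missing}")
    return np.array([offsets.loc[k] for k in keys], dtype=float)


def apply_loading_scaling(sites: SiteAbundanceMatrix, offsets: pd.Series) -> SiteAbundanceMatrix:
    """Subtract per-channel loading offsets from a log2 site matrix."""
    if sites.scale != "log2":
        raise ValueError("apply_loading_scaling expects log2 data")
    vec = _match_offsets(sites, offsets)
    res = sites._clone(sites.data.sub(pd.Series(vec, index=sites.data.columns), axis=1))
    res.record_step("loading_scale")
    return res


def apply_loading_scaling_linear(sites: SiteAbundanceMatrix, offsets: pd.Series) -> SiteAbundanceMatrix:
    """Divide a linear site matrix by 2^offset per channel (the linear-scale
    equivalent of the log2 offset subtraction), for the occupancy branch."""
    if sites.scale != "linear":
        raise ValueError("apply_loading_scaling_linear expects linear data")
    vec = _match_offsets(sites, offsets)
    res = sites._clone(sites.data.div(pd.Series(2.0 ** vec, index=sites.data.columns), axis=1))
    res.record_step("loading_scale")
    return res


def subtract_protein_abundance(
    sites: SiteAbundanceMatrix, proteins: AbundanceMatrix, designs: list[PlexDesign] | None = None
) -> SiteAbundanceMatrix:
    """Subtract each parent protein's *per-condition mean* normalized
    abundance from its sites' channels, leaving PTM-specific signal.

    Sites whose parent protein was not quantified are left unadjusted and
    recorded in ``orphan_sites``.
    """
    if sites.scale != "log2" or proteins.scale != "log2":
        raise ValueError("both matrices must be log2-normalized")
    cond_means = {}
    for cond in proteins.conditions:
        cols = proteins.condition_columns(cond)
        cond_means[cond] = proteins.data[cols].mean(axis=1)
    adjusted = sites.data.copy()
    parents = pd.Series({s: parse_site_key(s).protein_id for s in sites.data.index})
    orphans = list(parents.index[~parents.isin(proteins.data.index)])
    site_conditions = sites.channels["condition"]
    for cond, means in cond_means.items():
        cols = site_conditions.index[site_conditions == cond]
        if len(cols) == 0:
            continue
        shift = parents.map(means).fillna(0.0)  # orphan / unquantified parents: no shift
        adjusted[cols] = adjusted[cols].sub(shift, axis=0)
    res = sites._clone(adjusted)
    res.record_step("subtract_protein")
    res.adjusted_for_protein = True
    res.orphan_sites = orphans
    if orphans:
        log.info("subtract_protein_abundance: %d orphan sites left unadjusted", len(orphans))
    return res


def compute_occupancy(sites_linear: SiteAbundanceMatrix, designs: list[PlexDesign] | None = None) -> OccupancyTable:
    """Mean % thiol oxidation per (site, condition).

    Within each plex, a condition's oxidized-channel intensities are
    averaged and divided by the average of that plex's pooled total-thiol
    duplicate channels; ratios are then averaged across the plexes in which
    the site was quantified (plex-wide batch factors cancel within a plex).
    Rows whose denominator is missing or zero are omitted (count logged).
    Values above 100% are kept and flagged.
    """
    if sites_linear.scale != "linear":
        raise ValueError("occupancy is computed on linear intensities")
    if sites_linear.ptm_kind != "redox":
        raise ValueError("occupancy applies to the redox assay")
    if "loading_scale" not in sites_linear.applied_steps:
        log.warning("compute_occupancy: matrix has no loading scaling applied")
    meta = sites_linear.channels
    conditions = sites_linear.conditions
    per_cond_ratios: dict[str, list[pd.Series]] = {c: [] for c in conditions}
    for plex in sites_linear.plexes:
        in_plex = meta.index.get_level_values(0) == plex
        pool_cols = meta.index[in_plex & (meta["channel_class"] == "total_thiol_pool")]
        if len(pool_cols) == 0:
            raise ValueError(f"redox plex {plex} has no total_thiol_pool channels")
        pool_mean = sites_linear.data[pool_cols].mean(axis=1)
        pool_mean = pool_mean.where(pool_mean != 0)  # zero denominator -> omitted
        for cond in conditions:
            cols = meta.index[
                in_plex & (meta["condition"] == cond) & meta["channel_class"].isin(("sample", "bridge"))
            ]
            if len(cols) == 0:
                continue
            ox_mean = sites_linear.data[cols].mean(axis=1)
            per_cond_ratios[cond].append(100.0 * ox_mean / pool_mean)
    records = []
    n_dropped = 0
    for cond, ratios in per_cond_ratios.items():
        merged = pd.concat(ratios, axis=1).mean(axis=1)  # across plexes, NaN-skipping
        n_dropped += int(merged.isna().sum())
        for site, val in merged.dropna().items():
            records.append((site, cond, float(val), bool(val > 100.0)))
    if n_dropped:
        log.info("compute_occupancy: %d (site, condition) rows omitted", n_dropped)
    rows = pd.DataFrame(records, columns=["site", "condition", "mean_percent_oxidation", "over_100"])
    return OccupancyTable(rows=rows)


def normalize_site_matrix(
    psm: PSMTable,
    designs: list[PlexDesign],
    global_peptides_log2: AbundanceMatrix,
    proteins_normalized: AbundanceMatrix | None,
    ptm_kind: str,
) -> tuple[SiteAbundanceMatrix, SiteAbundanceMatrix | None]:
    """Run the full site-level chain.

    Returns ``(normalized, adjusted)`` where ``normalized`` is the
    loading-scaled, centered, batch-corrected log2 matrix and ``adjusted``
    additionally has per-condition parent-protein abundance subtracted
    (None when no protein matrix is supplied).
    """
    sites = aggregate_sites(psm, designs, ptm_kind)
    offsets = channel_loading_offsets(global_peptides_log2)
    sites_log2 = apply_loading_scaling(log2_transform(sites), offsets)
    sites_log2 = median_center_channels(sites_log2)
    sites_log2 = bridge_batch_correct(sites_log2)
    if proteins_normalized is None:
        return sites_log2, None
    adjusted = subtract_protein_abundance(sites_log2, proteins_normalized)
    return sites_log2, adjusted
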
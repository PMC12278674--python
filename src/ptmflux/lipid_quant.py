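"""Lipidomics preprocessing.

Missing peak heights (blank or zero cells) are set to 1 before
log-transformation and probabilistic quotient normalization (PQN), then
restored to missing — the same convention the lipid differential analysis
uses downstream.  PQN runs on linear intensities (the standard Dieterle
median-quotient formulation) with log2 applied afterwards; subclass sums and
row z-scaling serve the class-trend heatmaps.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, LipidAbundanceMatrix
from .io import LipidTable

__all__ = [
    "load_lipid_matrix",
    "pqn_normalize",
    "sum_subclass",
    "zscore_rows",
]

_SAMPLE_RE = re.compile(r"^(high|low)_(\d+)h_r(\d+)$")


def _sample_metadata(sample_ids: list[str]) -> pd.DataFrame:
    recs = []
    for sid in sample_ids:
        m = _SAMPLE_RE.match(sid)
        if m:
            nitrogen, t, rep = m.group(1), int(m.group(2)), int(m.group(3))
            cond = f"{nitrogen}_{t}h"
        else:
            nitrogen, t, rep, cond = None, np.nan, np.nan, None
        recs.append(
            dict(sample_id=sid, nitrogen=nitrogen, timepoint_h=t, replicate=rep,
                 assay="lipid", channel_class="sample", batch="lipidomics", condition=cond)
        )
    meta = pd.DataFrame(recs)
    meta.index = pd.MultiIndex.from_arrays(
        [["lipidomics"] * len(sample_ids), sample_ids], names=["plex_id", "channel_label"]
    )
    return meta.drop(columns=["sample_id"]).assign(sample_id=sample_ids)


def load_lipid_matrix(table: LipidTable, missing_to_one: bool = True) -> LipidAbundanceMatrix:
    """Build the lipid species x sample matrix.

    ``missing_mask`` records the originally-missing cells and is set exactly
    once here.  With ``missing_to_one`` (default) missing cells are assigned
    1 so the subsequent log transform maps them to 0, per the study rule.
    """
    intens = table.intensities()
    mask = intens.isna()
    data = intens.fillna(1.0) if missing_to_one else intens
    data.columns = pd.MultiIndex.from_arrays(
        [["lipidomics"] * len(table.sample_ids), table.sample_ids],
        names=["plex_id", "channel_label"],
    )
    mask.columns = data.columns
    meta = _sample_metadata(table.sample_ids)
    ann = table.rows.set_index("lipid_id")
    return LipidAbundanceMatrix(
        data=data, channels=meta, scale="linear", feature_kind="lipid",
        applied_steps=["load_lipids"] + (["missing_to_one"] if missing_to_one else []),
        class_map=ann["class"], subclass_map=ann["subclass"], missing_mask=mask,
    )


def pqn_normalize(m: LipidAbundanceMatrix, restore_missing: bool = True) -> LipidAbundanceMatrix:
    """Probabilistic quotient normalization on linear intensities.

    The reference spectrum is the per-feature median over samples; each
    sample is divided by the median quotient of its values against the
    reference.  Originally-missing cells (set to 1 beforehand) are restored
    to missing afterwards.
    """
    if m.scale != "linear":
        raise ValueError("pqn_normalize runs on linear intensities")
    data = m.data
    all_missing = m.missing_mask.all(axis=0) if m.missing_mask is not None else data.isna().all(axis=0)
    if all_missing.any():
        bad = list(data.columns[all_missing].get_level_values(1))
        raise ValueError(f"samples with all features missing: {bad}")
    reference = data.median(axis=1)
    quotients = data.div(reference, axis=0)
    dilution = quotients.median(axis=0)
    normalized = data.div(dilution, axis=1)
    if restore_missing and m.missing_mask is not None:
        normalized = normalized.mask(m.missing_mask)
    res = m._clone(normalized)
    res.record_step("pqn")
    return res


def sum_subclass(m: LipidAbundanceMatrix) -> AbundanceMatrix:
    """Summed peak heights per lipid subclass (missing cells contribute 0);
    subclasses without members are simply absent."""
    if m.scale != "linear":
        raise ValueError("sum_subclass expects linear intensities")
    sums = m.data.groupby(m.subclass_map.reindex(m.data.index)).sum()
    sums.index.name = "subclass"
    return AbundanceMatrix(
        data=sums, channels=m.channels, scale="linear", feature_kind="subclass",
        applied_steps=list(m.applied_steps) + ["sum_subclass"],
    )


def zscore_rows(m: AbundanceMatrix) -> AbundanceMatrix:
    """Scale each row to mean 0 and standard deviation 1 (sample SD, n-1)."""
    mu = m.data.mean(axis=1)
    sd = m.data.std(axis=1, ddof=1)
    degenerate = sd.isna() | (sd == 0)
    if degenerate.any():
        raise ValueError(f"constant rows cannot be z-scaled: {list(m.data.index[degenerate])}")
    res = m._clone(m.data.sub(mu, axis=0).div(sd, axis=0))
    res.record_step("zscore_rows")
    return res
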
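import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ptmflux.containers import AbundanceMatrix
from ptmflux.io import DESIGN_COLUMNS, PlexDesign, PSMTable
from ptmflux.simulate import EffectModel, SimConfig


def _design_rows(spec):
    """spec: list of (channel, sample_id, nitrogen, t, rep, assay, cls, batch)."""
    df = pd.DataFrame(spec, columns=DESIGN_COLUMNS[1:])
    df["timepoint_h"] = df["timepoint_h"].astype("Int64")
    df["replicate"] = df["replicate"].astype("Int64")
    return df


@pytest.fixture
def mini_redox_designs():
    """Two tiny redox plexes: 2 bridge (24 h), 2 sample (48/72 h), 2 pool, 1 empty."""
    designs = []
    for batch, tp in (("plex1", 48), ("plex2", 72)):
        spec = [
            ("ch1", "high_24h_r1", "high", 24, 1, "redox", "bridge", batch),
            ("ch2", "low_24h_r1", "low", 24, 1, "redox", "bridge", batch),
            ("ch3", f"high_{tp}h_r1", "high", tp, 1, "redox", "sample", batch),
            ("ch4", f"low_{tp}h_r1", "low", tp, 1, "redox", "sample", batch),
            ("ch5", "total_thiol_pool_a", "none", None, None, "redox", "total_thiol_pool", batch),
            ("ch6", "total_thiol_pool_b", "none", None, None, "redox", "total_thiol_pool", batch),
            ("ch7", "", "none", None, None, "redox", "empty", batch),
        ]
        designs.append(PlexDesign(plex_id=f"redox_{batch}", rows=_design_rows(spec)))
    return designs


@pytest.fixture
def make_matrix(mini_redox_designs):
    """Factory: AbundanceMatrix over the mini redox design from a per-channel dict."""
    from ptmflux.containers import channel_table

    meta = channel_table(mini_redox_designs)

    def _make(values: dict[str, list], scale="log2", cls=AbundanceMatrix, **kw):
        data = pd.DataFrame(values, index=meta.index).T
        data.index.name = None
        return cls(data=data, channels=meta, scale=scale,
                   applied_steps=kw.pop("applied_steps", ["loaded"]), **kw)

    return _make


def make_psm(designs, rows):
    """rows: list of dicts with plex_id, peptide, protein_id, site_keys,
    fdr_pass and channel intensities."""
    labels = sorted({lab for d in designs for lab in d.rows["channel_label"]})
    recs = []
    for r in rows:
        rec = {"plex_id": r["plex_id"], "peptide": r["peptide"],
               "protein_id": r["protein_id"], "site_keys": r.get("site_keys", ""),
               "fdr_pass": r.get("fdr_pass", True)}
        for lab in labels:
            rec[lab] = r.get(lab, np.nan)
        recs.append(rec)
    return PSMTable(rows=pd.DataFrame(recs), channel_labels=labels)


def flat_config(seed=0, **overrides):
    """A degenerate generator config: no effects, no noise, unit loadings,
    no batch shift, flat occupancy factors — every downstream fold change
    should be exactly zero."""
    base = dict(
        seed=seed, n_proteins=30, n_cys_sites=40, n_phospho_sites=40,
        noise_cv=0.0,
        effects={"global": EffectModel(0.0, 1.0), "redox": EffectModel(0.0, 1.0),
                 "phospho": EffectModel(0.0, 1.0)},
        pi_low_n_factor=1.0, pi_time_factors={24: 1.0, 48: 1.0, 72: 1.0},
        channel_loading_log2_sd=0.0,
        batch_log2_offsets={"plex1": 0.0, "plex2": 0.0},
        frac_fdr_fail=0.0, frac_composite_phospho=0.0,
        lipid_trend_scale=0.0, lipid_dropout_quantile=0.0,
        n_tg_coupled_sites=0,
    )
    base.update(overrides)
    return SimConfig(**base)
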
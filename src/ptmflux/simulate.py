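"""Synthetic multi-omics studies with known ground truth.

The generator emulates the structure of a nitrogen-limitation timecourse in
an oleaginous yeast: a 2x3 condition grid (high/low nitrogen x 24/48/72 h,
n = 3 biological replicates), two TMT-18 plexes per assay sharing the six
24 h samples as bridge (technical-replicate) channels, pooled total-thiol
reference duplicates in every plex, empty buffer channels, per-channel
loading factors, a per-plex batch factor, multiplicative log-normal noise,
and a lipidome whose class composition matches the study's 206 identified
species (172 glycerophospholipids+glycerolipids, 19 sphingolipids, 14 fatty
acyls, 1 prenol lipid).

Measurement model (linear reporter intensities):

* global:   I = 2^(protein log2) * peptide efficiency * loading * batch * noise
* redox:    I = pi(site, condition) * 2^(protein log2) * efficiency * ...
* pool:     I = mean over all study samples of the total (pi = 1) signal
* phospho:  I = stoichiometry * 2^(protein log2) * efficiency * ...
* lipid:    I = 2^(lipid log2 level) * noise, low quantile -> missing

Thiol-oxidation occupancy pi defaults give group mean occupancies in the
10-15% band, ~25% higher under low nitrogen at 24/48 h and 1.5x higher at
72 h than at 24 h.  Enrichment (RAC/IMAC) is treated as lossless — a
documented simplification.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    LipidTable,
    PlexDesign,
    PSMTable,
    SetCollection,
    DESIGN_COLUMNS,
)

__all__ = ["EffectModel", "SimConfig", "GroundTruth", "SimulatedStudy",
           "simulate_study", "simulate_null", "write_study", "CONDITIONS"]

CONDITIONS = ["high_24h", "low_24h", "high_48h", "low_48h", "high_72h", "low_72h"]

# (class, subclass, n species, low-vs-high nitrogen log2FC, log2 slope per day)
DEFAULT_LIPIDOME = [
    ("GL", "TG", 60, 1.5, 0.6),
    ("GL", "DG", 20, 1.2, 0.5),
    ("GP", "PC", 25, -1.0, -0.4),
    ("GP", "PE", 20, -1.0, -0.4),
    ("GP", "PI", 12, -0.8, -0.3),
    ("GP", "PS", 8, -0.8, -0.3),
    ("GP", "PG", 7, -0.5, -0.2),
    ("GP", "PA", 6, -0.5, -0.2),
    ("GP", "LPC", 8, -0.6, -0.3),
    ("GP", "LPE", 6, -0.6, -0.3),
    ("SL", "Cer", 12, -1.2, -0.3),
    ("SL", "HexCer", 7, -1.0, -0.3),
    ("FA", "FA", 10, -0.8, 0.0),
    ("FA", "FAHFA", 4, -2.5, 0.0),
    ("PR", "CoQ", 1, 1.0, 0.3),
]


@dataclass(frozen=True)
class EffectModel:
    """Differential-effect settings for one omic layer: the fraction of
    features given a nitrogen effect and the log2 effect-size distribution
    (Normal(0, effect_sd), or +-``fixed`` with random sign when set)."""

    frac_differential: float = 0.1
    effect_sd: float = 1.0
    fixed: float | None = None

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.fixed is not None:
            signs = np.ones(n)
            signs[: n // 2] = -1.0
            rng.shuffle(signs)
            return signs * self.fixed
        return rng.normal(0.0, self.effect_sd, n)


@dataclass
class SimConfig:
    """Study-generator settings; the defaults are the study conditions."""

    seed: int
    n_proteins: int = 300
    peptides_per_protein: int = 3
    n_cys_sites: int = 400
    n_phospho_sites: int = 600
    replicates: int = 3
    noise_cv: float = 0.1
    effects: dict[str, EffectModel] = field(default_factory=lambda: {
        "global": EffectModel(0.10, 1.0),
        "redox": EffectModel(0.15, 1.0),
        "phospho": EffectModel(0.15, 1.0),
    })
    # protein baseline
    protein_log2_mean: float = 20.0
    protein_log2_sd: float = 2.0
    peptide_eff_sigma: float = 0.5  # ln-space SD of ionization efficiency
    # occupancy model
    pi_log2_mean: float = np.log2(0.095)
    pi_log2_sd: float = 0.45
    pi_low_n_factor: float = 1.2           # at 24 h and 48 h
    pi_time_factors: dict[int, float] = field(default_factory=lambda: {24: 1.0, 48: 1.15, 72: 1.45})
    stoich_log2_mean: float = np.log2(0.3)
    stoich_log2_sd: float = 0.5
    # technical structure
    channel_loading_log2_sd: float = 0.15
    loading_overrides: dict[tuple[str, str], float] = field(default_factory=dict)
    batch_log2_offsets: dict[str, float] = field(default_factory=lambda: {"plex1": 0.0, "plex2": 0.3})
    frac_fdr_fail: float = 0.05
    frac_composite_phospho: float = 0.05
    # lipidome
    lipidome: list[tuple] = field(default_factory=lambda: list(DEFAULT_LIPIDOME))
    lipid_log2_mean: float = 18.0
    lipid_log2_sd: float = 1.5
    lipid_trend_scale: float = 1.0
    lipid_dropout_quantile: float = 0.02
    # redox-lipid coupling
    n_tg_coupled_sites: int = 20
    tg_coupling_gamma: float = 1.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_proteins", "peptides_per_protein", "n_cys_sites",
                     "n_phospho_sites", "replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass
class GroundTruth:
    """True per-condition levels and technical factors behind a simulated
    study, serialized alongside outputs so recovery tests are self-contained."""

    protein_log2: pd.DataFrame          # protein x condition
    site_occupancy: pd.DataFrame        # cys site x condition, in [0, 1]
    phospho_stoichiometry: pd.DataFrame
    lipid_log2: pd.DataFrame
    channel_loading: pd.Series          # (batch, channel_label) -> positive factor
    batch_offset: dict[str, float]      # batch -> log2 offset
    noise_cv: float
    differential: dict[str, frozenset]  # omic -> differential feature ids
    peptide_efficiency: pd.Series       # peptide -> efficiency
    tg_coupled_sites: frozenset

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for name, frame in (("protein_log2", self.protein_log2),
                            ("site_occupancy", self.site_occupancy),
                            ("phospho_stoichiometry", self.phospho_stoichiometry),
                            ("lipid_log2", self.lipid_log2)):
            long = frame.reset_index(names="feature").melt(
                id_vars="feature", var_name="condition", value_name="value")
            long.insert(0, "quantity", name)
            parts.append(long)
        tech = pd.DataFrame({
            "quantity": "channel_loading",
            "feature": [f"{b}:{c}" for b, c in self.channel_loading.index],
            "condition": "",
            "value": self.channel_loading.to_numpy(),
        })
        batch = pd.DataFrame({
            "quantity": "batch_offset",
            "feature": list(self.batch_offset),
            "condition": "",
            "value": list(self.batch_offset.values()),
        })
        return pd.concat(parts + [tech, batch], ignore_index=True)


@dataclass
class SimulatedStudy:
    designs: list[PlexDesign]
    psm: dict[str, PSMTable]            # assay -> table
    lipids: LipidTable
    truth: GroundTruth
    protein_sets: SetCollection
    lipid_sets: SetCollection

    @property
    def designs_by_assay(self) -> dict[str, list[PlexDesign]]:
        out: dict[str, list[PlexDesign]] = {}
        for d in self.designs:
            out.setdefault(d.assay, []).append(d)
        return out


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def _sample_id(nitrogen: str, t: int, rep: int) -> str:
    return f"{nitrogen}_{t}h_r{rep}"


def _build_designs(cfg: SimConfig) -> list[PlexDesign]:
    designs = []
    reps = range(1, cfg.replicates + 1)
    for assay in ("global", "redox", "phospho"):
        for batch, tp in (("plex1", 48), ("plex2", 72)):
            rows = []
            ch = 1
            for n in ("high", "low"):
                for r in reps:
                    rows.append((f"ch{ch:02d}", _sample_id(n, 24, r), n, 24, r, assay, "bridge", batch))
                    ch += 1
            for n in ("high", "low"):
                for r in reps:
                    rows.append((f"ch{ch:02d}", _sample_id(n, tp, r), n, tp, r, assay, "sample", batch))
                    ch += 1
            for dup in ("a", "b"):
                rows.append((f"ch{ch:02d}", f"total_thiol_pool_{dup}", "none", None, None, assay,
                             "total_thiol_pool", batch))
                ch += 1
            while ch <= 18:
                rows.append((f"ch{ch:02d}", "", "none", None, None, assay, "empty", batch))
                ch += 1
            df = pd.DataFrame(rows, columns=DESIGN_COLUMNS[1:])
            df["timepoint_h"] = df["timepoint_h"].astype("Int64")
            df["replicate"] = df["replicate"].astype("Int64")
            designs.append(PlexDesign(plex_id=f"{assay}_{batch}", rows=df))
    return designs


# ---------------------------------------------------------------------------
# Truth construction
# ---------------------------------------------------------------------------

def _condition_parts(cond: str) -> tuple[str, int]:
    n, t = cond.split("_")
    return n, int(t[:-1])


def _protein_truth(cfg: SimConfig, rng: np.random.Generator):
    proteins = [f"RT_{i:04d}" for i in range(1, cfg.n_proteins + 1)]
    base = rng.normal(cfg.protein_log2_mean, cfg.protein_log2_sd, cfg.n_proteins)
    eff_cfg = cfg.effects.get("global", EffectModel(0, 1))
    n_diff = int(round(eff_cfg.frac_differential * cfg.n_proteins))
    diff_idx = rng.choice(cfg.n_proteins, size=n_diff, replace=False)
    effects = np.zeros(cfg.n_proteins)
    effects[diff_idx] = eff_cfg.draw(rng, n_diff)
    table = {}
    for cond in CONDITIONS:
        nitrogen, _ = _condition_parts(cond)
        table[cond] = base + effects * (nitrogen == "low")
    frame = pd.DataFrame(table, index=proteins)
    differential = frozenset(np.asarray(proteins)[diff_idx])
    return frame, differential


def _lipid_trend_log2(cfg: SimConfig) -> pd.DataFrame:
    """Per-subclass condition log2 shifts (shared by member species)."""
    rows = {}
    for _, subclass, _, nit_lfc, slope in cfg.lipidome:
        shifts = []
        for cond in CONDITIONS:
            nitrogen, t = _condition_parts(cond)
            shifts.append(cfg.lipid_trend_scale * (nit_lfc * (nitrogen == "low") + slope * (t - 24) / 24.0))
        rows[subclass] = shifts
    return pd.DataFrame(rows, index=CONDITIONS).T


def _site_truth(cfg: SimConfig, rng: np.random.Generator, proteins: list[str]):
    """Cysteine-site occupancies, including the TG-coupled subset whose log2
    occupancy is affine in the TG subclass trajectory."""
    host = rng.choice(len(proteins), size=cfg.n_cys_sites, replace=True)
    positions = rng.integers(5, 900, size=cfg.n_cys_sites)
    sites = []
    seen = set()
    for h, pos in zip(host, positions):
        key = (proteins[h], int(pos))
        while key in seen:
            key = (key[0], key[1] + 1)
        seen.add(key)
        sites.append(f"{key[0]}_C{key[1]}")
    pi0 = 2.0 ** rng.normal(cfg.pi_log2_mean, cfg.pi_log2_sd, cfg.n_cys_sites)
    eff_cfg = cfg.effects.get("redox", EffectModel(0, 1))
    n_diff = int(round(eff_cfg.frac_differential * cfg.n_cys_sites))
    diff_idx = rng.choice(cfg.n_cys_sites, size=n_diff, replace=False)
    effects = np.zeros(cfg.n_cys_sites)
    effects[diff_idx] = eff_cfg.draw(rng, n_diff)
    n_coupled = min(cfg.n_tg_coupled_sites, cfg.n_cys_sites)
    coupled_idx = rng.choice(cfg.n_cys_sites, size=n_coupled, replace=False)
    coupled = np.zeros(cfg.n_cys_sites, dtype=bool)
    coupled[coupled_idx] = True
    tg_trend = _lipid_trend_log2(cfg).loc["TG"] if any(s[1] == "TG" for s in cfg.lipidome) else None
    table = {}
    for cond in CONDITIONS:
        nitrogen, t = _condition_parts(cond)
        factor = cfg.pi_time_factors.get(t, 1.0)
        if nitrogen == "low" and t in (24, 48):
            factor *= cfg.pi_low_n_factor
        pi = pi0 * factor * 2.0 ** (effects * (nitrogen == "low"))
        if tg_trend is not None:
            # coupled sites start from half their baseline so the coupled
            # trajectory stays inside the physiological occupancy range
            pi = np.where(coupled, 0.5 * pi0 * 2.0 ** (cfg.tg_coupling_gamma * tg_trend[cond]), pi)
        table[cond] = np.clip(pi, 0.002, 0.95)
    frame = pd.DataFrame(table, index=sites)
    differential = frozenset(np.asarray(sites)[diff_idx]) | frozenset(np.asarray(sites)[coupled])
    return frame, differential, frozenset(np.asarray(sites)[coupled])


def _phospho_truth(cfg: SimConfig, rng: np.random.Generator, proteins: list[str]):
    host = rng.choice(len(proteins), size=cfg.n_phospho_sites, replace=True)
    positions = rng.integers(5, 1200, size=cfg.n_phospho_sites)
    aas = rng.choice(list("STY"), size=cfg.n_phospho_sites, p=[0.6, 0.3, 0.1])
    composite = rng.random(cfg.n_phospho_sites) < cfg.frac_composite_phospho
    sites, seen = [], set()
    for h, pos, aa, comp in zip(host, positions, aas, composite):
        pos = int(pos)
        key = (proteins[h], pos)
        while key in seen:
            pos += 2
            key = (proteins[h], pos)
        seen.add(key)
        if comp:
            aa2 = "T" if aa != "T" else "S"
            sites.append(f"{proteins[h]}_{aa}{pos};{aa2}{pos + 1}")
        else:
            sites.append(f"{proteins[h]}_{aa}{pos}")
    stoich0 = np.clip(2.0 ** rng.normal(cfg.stoich_log2_mean, cfg.stoich_log2_sd, cfg.n_phospho_sites),
                      0.01, 1.0)
    eff_cfg = cfg.effects.get("phospho", EffectModel(0, 1))
    n_diff = int(round(eff_cfg.frac_differential * cfg.n_phospho_sites))
    diff_idx = rng.choice(cfg.n_phospho_sites, size=n_diff, replace=False)
    effects = np.zeros(cfg.n_phospho_sites)
    effects[diff_idx] = eff_cfg.draw(rng, n_diff)
    table = {}
    for cond in CONDITIONS:
        nitrogen, _ = _condition_parts(cond)
        table[cond] = np.clip(stoich0 * 2.0 ** (effects * (nitrogen == "low")), 0.005, 1.0)
    frame = pd.DataFrame(table, index=sites)
    return frame, frozenset(np.asarray(sites)[diff_idx])


def _lipid_truth(cfg: SimConfig, rng: np.random.Generator):
    trend = _lipid_trend_log2(cfg)
    ids, classes, subclasses = [], [], []
    for cls, subclass, n, _, _ in cfg.lipidome:
        for i in range(1, n + 1):
            ids.append(f"{subclass}_{i:02d}")
            classes.append(cls)
            subclasses.append(subclass)
    base = rng.normal(cfg.lipid_log2_mean, cfg.lipid_log2_sd, len(ids))
    table = {}
    for cond in CONDITIONS:
        table[cond] = base + np.array([trend.loc[sc, cond] for sc in subclasses])
    frame = pd.DataFrame(table, index=ids)
    ann = pd.DataFrame({"lipid_id": ids, "class": classes, "subclass": subclasses})
    return frame, ann


# ---------------------------------------------------------------------------
# Intensity emission
# ---------------------------------------------------------------------------

def _noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=size)


def _channel_loading(cfg: SimConfig, rng: np.random.Generator, designs: list[PlexDesign]) -> pd.Series:
    keys = []
    for batch in ("plex1", "plex2"):
        d = next(x for x in designs if x.batch == batch)
        for lab in d.channels()["channel_label"]:
            keys.append((batch, lab))
    vals = 2.0 ** rng.normal(0.0, cfg.channel_loading_log2_sd, len(keys))
    loading = pd.Series(vals, index=pd.MultiIndex.from_tuples(keys, names=["batch", "channel_label"]))
    for key, v in cfg.loading_overrides.items():
        loading.loc[key] = v
    return loading


def _emit_psm(cfg, rng, designs_for_assay, features: pd.DataFrame, truth_level: pd.DataFrame,
              protein_of: pd.Series, loading: pd.Series, assay: str) -> PSMTable:
    """Build the PSM table of one assay.

    ``features`` has index = peptide id and columns ``protein_id, site_keys``;
    ``truth_level`` is the feature x condition *linear* multiplier applied to
    the parent protein level (1 for global; pi or stoichiometry for PTMs).
    """
    rows = features.copy()
    rows.insert(0, "peptide", rows.index)
    all_frames = []
    protein_lin = 2.0 ** protein_of  # protein x condition linear level
    pooled = protein_lin.mean(axis=1)  # unweighted mean over study samples
    for d in designs_for_assay:
        batch_factor = 2.0 ** cfg.batch_log2_offsets.get(d.batch, 0.0)
        block = rows.copy()
        block.insert(0, "plex_id", d.plex_id)
        parent_lin = protein_lin.loc[block["protein_id"]].to_numpy()
        parent_pooled = pooled.loc[block["protein_id"]].to_numpy()
        eff = block["efficiency"].to_numpy()
        for _, chan in d.rows.iterrows():
            lab = chan["channel_label"]
            cls = chan["channel_class"]
            if cls == "empty":
                block[lab] = 0.0
                continue
            load = loading.loc[(d.batch, lab)]
            if cls == "total_thiol_pool":
                if assay == "phospho":
                    # pooled phospho-enriched material: stoichiometry-weighted
                    level = (truth_level.to_numpy() * parent_lin).mean(axis=1)
                else:
                    # -NEM pool: all cysteines reduced, full protein signal
                    level = parent_pooled
            else:
                cond = f"{chan['nitrogen']}_{int(chan['timepoint_h'])}h"
                ci = CONDITIONS.index(cond)
                level = truth_level.iloc[:, ci].to_numpy() * parent_lin[:, ci]
            block[lab] = level * eff * load * batch_factor * _noise(rng, cfg.noise_cv, len(block))
        all_frames.append(block)
    out = pd.concat(all_frames, ignore_index=True)
    # decoy rows failing the FDR filter
    n_fail = int(round(cfg.frac_fdr_fail * len(out)))
    fdr_pass = np.ones(len(out), dtype=bool)
    if n_fail:
        fail_idx = rng.choice(len(out), size=n_fail, replace=False)
        fdr_pass[fail_idx] = False
    out["fdr_pass"] = fdr_pass
    channel_labels = [lab for d in designs_for_assay for lab in d.rows["channel_label"]]
    channel_labels = list(dict.fromkeys(channel_labels))
    out = out.drop(columns=["efficiency"])
    meta = ["plex_id", "peptide", "protein_id", "site_keys", "fdr_pass"]
    return PSMTable(rows=out[meta + channel_labels], channel_labels=channel_labels)


def _make_sets(rng, proteins: list[str], coupled_proteins: set[str],
               lipid_ann: pd.DataFrame) -> tuple[SetCollection, SetCollection]:
    shuffled = list(proteins)
    rng.shuffle(shuffled)
    n_per = max(5, len(proteins) // 10)
    psets = {}
    for i in range(0, len(shuffled), n_per):
        chunk = shuffled[i:i + n_per]
        if len(chunk) >= 2:
            psets[f"pathway_{i // n_per + 1:02d}"] = (f"synthetic pathway {i // n_per + 1}",
                                                      frozenset(chunk))
    extras = rng.choice(proteins, size=min(10, len(proteins)), replace=False)
    psets["fatty_acid_metabolism"] = (
        "proteins whose oxidized sites track storage-lipid accumulation",
        frozenset(coupled_proteins) | frozenset(extras),
    )
    lsets = {
        sc: (f"{sc} species", frozenset(g["lipid_id"]))
        for sc, g in lipid_ann.groupby("subclass") if len(g) >= 2
    }
    return SetCollection(psets), SetCollection(lsets)


def simulate_study(cfg: SimConfig) -> SimulatedStudy:
    """Generate a complete synthetic study (designs, three PSM tables, lipid
    table, set collections) with serializable ground truth."""
    rng = np.random.default_rng(cfg.seed)
    designs = _build_designs(cfg)
    protein_truth, diff_global = _protein_truth(cfg, rng)
    proteins = list(protein_truth.index)
    site_truth, diff_redox, coupled = _site_truth(cfg, rng, proteins)
    phospho_truth, diff_phospho = _phospho_truth(cfg, rng, proteins)
    lipid_truth, lipid_ann = _lipid_truth(cfg, rng)
    loading = _channel_loading(cfg, rng, designs)

    by_assay = {}
    for d in designs:
        by_assay.setdefault(d.assay, []).append(d)

    # global peptides: peptides_per_protein per protein, no site keys
    pep_ids, pep_prot = [], []
    for p in proteins:
        for j in range(1, cfg.peptides_per_protein + 1):
            pep_ids.append(f"{p}_pep{j}")
            pep_prot.append(p)
    eff_global = pd.Series(rng.lognormal(0.0, cfg.peptide_eff_sigma, len(pep_ids)), index=pep_ids)
    feat_global = pd.DataFrame({"protein_id": pep_prot, "site_keys": "",
                                "efficiency": eff_global}, index=pep_ids)
    ones = pd.DataFrame(1.0, index=pep_ids, columns=CONDITIONS)
    psm_global = _emit_psm(cfg, rng, by_assay["global"], feat_global, ones,
                           protein_truth, loading, "global")

    # redox: one cysteine peptide per site
    def _ptm_features(truth: pd.DataFrame) -> pd.DataFrame:
        sites = list(truth.index)
        eff = rng.lognormal(0.0, cfg.peptide_eff_sigma, len(sites))
        return pd.DataFrame(
            {"protein_id": [s.rsplit("_", 1)[0] for s in sites],
             "site_keys": sites, "efficiency": eff},
            index=[f"{s}_pep" for s in sites],
        )

    feat_redox = _ptm_features(site_truth)
    psm_redox = _emit_psm(cfg, rng, by_assay["redox"], feat_redox,
                          site_truth.set_axis(feat_redox.index), protein_truth, loading, "redox")

    feat_phos = _ptm_features(phospho_truth)
    psm_phospho = _emit_psm(cfg, rng, by_assay["phospho"], feat_phos,
                            phospho_truth.set_axis(feat_phos.index), protein_truth, loading, "phospho")

    # lipidomics: 18 label-free samples
    sample_ids = [_sample_id(n, t, r) for t in (24, 48, 72) for n in ("high", "low")
                  for r in range(1, cfg.replicates + 1)]
    lin = {}
    for sid in sample_ids:
        cond = sid.rsplit("_r", 1)[0]
        lin[sid] = (2.0 ** lipid_truth[cond].to_numpy()) * _noise(rng, cfg.noise_cv, len(lipid_truth))
    lipid_vals = pd.DataFrame(lin, index=lipid_truth.index)
    if cfg.lipid_dropout_quantile > 0:
        cut = np.nanquantile(lipid_vals.to_numpy(), cfg.lipid_dropout_quantile)
        lipid_vals = lipid_vals.where(lipid_vals > cut)
    lipid_rows = pd.concat([lipid_ann.set_index("lipid_id"), lipid_vals], axis=1).reset_index(names="lipid_id")
    lipids = LipidTable(rows=lipid_rows, sample_ids=sample_ids)

    diff_lipids = frozenset(
        lid for lid, sc in zip(lipid_ann["lipid_id"], lipid_ann["subclass"])
        if cfg.lipid_trend_scale != 0
    )
    truth = GroundTruth(
        protein_log2=protein_truth, site_occupancy=site_truth,
        phospho_stoichiometry=phospho_truth, lipid_log2=lipid_truth,
        channel_loading=loading, batch_offset=dict(cfg.batch_log2_offsets),
        noise_cv=cfg.noise_cv,
        differential={"global": diff_global, "redox": diff_redox,
                      "phospho": diff_phospho, "lipid": diff_lipids},
        peptide_efficiency=pd.concat([eff_global, feat_redox["efficiency"],
                                      feat_phos["efficiency"]]),
        tg_coupled_sites=coupled,
    )
    coupled_proteins = {s.rsplit("_", 1)[0] for s in coupled}
    protein_sets, lipid_sets = _make_sets(rng, proteins, coupled_proteins, lipid_ann)
    return SimulatedStudy(designs=designs,
                          psm={"global": psm_global, "redox": psm_redox, "phospho": psm_phospho},
                          lipids=lipids, truth=truth,
                          protein_sets=protein_sets, lipid_sets=lipid_sets)


def simulate_null(cfg: SimConfig) -> SimulatedStudy:
    """Same generative process with every condition effect switched off
    (flat occupancies/stoichiometries/lipid trends, no differential
    features); technical structure (loadings, batch, noise) is retained.
    Used for type-I-error and FDR calibration."""
    null_cfg = dataclasses.replace(
        cfg,
        effects={k: EffectModel(0.0, v.effect_sd) for k, v in cfg.effects.items()},
        pi_low_n_factor=1.0,
        pi_time_factors={24: 1.0, 48: 1.0, 72: 1.0},
        lipid_trend_scale=0.0,
        n_tg_coupled_sites=0,
    )
    return simulate_study(null_cfg)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write designs, PSM tables, lipid table, set collections and
    ground_truth.tsv into ``outdir``; returns the path map."""
    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["design"] = outdir / "design.tsv"
    _io.write_design(study.designs, paths["design"])
    for assay, table in study.psm.items():
        paths[f"psm_{assay}"] = outdir / f"psm_{assay}.tsv"
        _io.write_psm_table(table, paths[f"psm_{assay}"])
    paths["lipids"] = outdir / "lipids.csv"
    _io.write_lipid_table(study.lipids, paths["lipids"])
    paths["protein_sets"] = outdir / "protein_sets.gmt"
    _io.write_gmt(study.protein_sets, paths["protein_sets"])
    paths["lipid_sets"] = outdir / "lipid_sets.gmt"
    _io.write_gmt(study.lipid_sets, paths["lipid_sets"])
    paths["ground_truth"] = outdir / "ground_truth.tsv"
    study.truth.to_frame().to_csv(paths["ground_truth"], sep="\t", index=False)
    return paths
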
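"""End-to-end orchestration: simulate/load -> quantify -> occupancy ->
differential statistics -> enrichment -> redox-lipid integration.

Every stage writes its outputs as files and appends one entry to the run
manifest (row counts, dropped-feature counts, output digests), so a run can
be audited and reproduced from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diff_stats, enrich, global_quant, lipid_quant, ptm_quant
from .containers import AbundanceMatrix
from .io import FilterConfig, write_design
from .simulate import SimConfig, SimulatedStudy, simulate_study, write_study

__all__ = ["RunManifest", "run_all", "pca_scores", "sample_correlation"]

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    seed: int
    config: dict
    entries: list[dict] = field(default_factory=list)

    def add(self, stage: str, outputs: dict[str, Path], n_rows: int, n_dropped: int = 0) -> None:
        self.entries.append({
            "stage": stage,
            "outputs": {k: str(p) for k, p in outputs.items()},
            "digests": {k: _digest(p) for k, p in outputs.items()},
            "n_rows": int(n_rows),
            "n_dropped": int(n_dropped),
        })

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_matrix(m: AbundanceMatrix, path: Path) -> None:
    out = m.data.copy()
    out.columns = [f"{p}:{c}" for p, c in out.columns]
    out.to_csv(path, sep="\t")
    with open(path.with_suffix(".steps.txt"), "w") as fh:
        fh.write("\n".join(m.applied_steps) + "\n")


def pca_scores(m: AbundanceMatrix, n_components: int = 2) -> pd.DataFrame:
    """Descriptive SVD-based PCA sample scores on complete features."""
    complete = m.data.dropna(axis=0)
    X = complete.to_numpy(dtype=float).T
    X = X - X.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, len(s))
    scores = X @ vt[:k].T
    return pd.DataFrame(scores, index=[f"{p}:{c}" for p, c in m.data.columns],
                        columns=[f"PC{i + 1}" for i in range(k)])


def sample_correlation(m: AbundanceMatrix) -> pd.DataFrame:
    """Descriptive channel-by-channel Pearson correlation matrix."""
    df = m.data.copy()
    df.columns = [f"{p}:{c}" for p, c in df.columns]
    return df.corr(method="pearson")


def run_all(sim_config: SimConfig, outdir: str | Path,
            cfg: FilterConfig | None = None, moderate: bool = True) -> tuple[RunManifest, dict]:
    """Run the full synthetic-study analysis into ``outdir``.

    Returns the manifest and a dict of in-memory results (matrices,
    DiffResults, enrichment tables, the integration selection).
    """
    cfg = cfg or FilterConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=sim_config.seed, config={
        "sim": {k: str(v) for k, v in dataclasses.asdict(sim_config).items()},
        "filters": dataclasses.asdict(cfg),
    })
    results: dict = {}

    # -- stage 1: simulate --------------------------------------------------
    study = simulate_study(sim_config)
    paths = write_study(study, outdir / "inputs")
    manifest.add("simulate", paths, n_rows=sum(len(t) for t in study.psm.values()))
    results["study"] = study

    # -- stage 2: global quantification ------------------------------------
    gdesigns = study.designs_by_assay["global"]
    g_psm = study.psm["global"]
    g_psm = type(g_psm)(rows=g_psm.rows[g_psm.rows["fdr_pass"]].reset_index(drop=True),
                        channel_labels=g_psm.channel_labels)
    peptides_log2 = global_quant.log2_transform(global_quant.rollup_peptide(g_psm, gdesigns))
    proteins = global_quant.rollup_protein(g_psm, gdesigns)
    proteins = global_quant.median_center_channels(
        global_quant.bridge_batch_correct(global_quant.log2_transform(proteins)))
    p_path = outdir / "global_proteins.tsv"
    _write_matrix(proteins, p_path)
    manifest.add("global_quant", {"matrix": p_path}, n_rows=len(proteins.data))
    results["proteins"] = proteins
    results["peptides_log2"] = peptides_log2

    # -- stage 3/4: PTM quantification + occupancy --------------------------
    site_matrices = {}
    for kind in ("redox", "phospho"):
        designs = study.designs_by_assay[kind]
        psm = study.psm[kind]
        psm = type(psm)(rows=psm.rows[psm.rows["fdr_pass"]].reset_index(drop=True),
                        channel_labels=psm.channel_labels)
        normalized, adjusted = ptm_quant.normalize_site_matrix(
            psm, designs, peptides_log2, proteins, kind)
        site_matrices[kind] = (normalized, adjusted)
        for tag, mat in (("normalized", normalized), ("adjusted", adjusted)):
            _write_matrix(mat, outdir / f"{kind}_sites_{tag}.tsv")
        manifest.add(f"{kind}_quant",
                     {"normalized": outdir / f"{kind}_sites_normalized.tsv",
                      "adjusted": outdir / f"{kind}_sites_adjusted.tsv"},
                     n_rows=len(normalized.data), n_dropped=len(adjusted.orphan_sites))
        if kind == "redox":
            offsets = ptm_quant.channel_loading_offsets(peptides_log2)
            linear = ptm_quant.apply_loading_scaling_linear(
                ptm_quant.aggregate_sites(psm, designs, "redox"), offsets)
            occupancy = ptm_quant.compute_occupancy(linear)
            occ_path = outdir / "occupancy.tsv"
            occupancy.rows.to_csv(occ_path, sep="\t", index=False)
            manifest.add("occupancy", {"table": occ_path}, n_rows=len(occupancy.rows))
            results["occupancy"] = occupancy
    results["sites"] = site_matrices

    # -- stage 5: lipidomics -------------------------------------------------
    lipid_lin = lipid_quant.pqn_normalize(lipid_quant.load_lipid_matrix(study.lipids))
    subclass = lipid_quant.sum_subclass(lipid_lin)  # missing cells contribute 0
    lipid_log2 = global_quant.log2_transform(lipid_lin)
    _write_matrix(lipid_log2, outdir / "lipids_normalized_log2.tsv")
    _write_matrix(subclass, outdir / "lipid_subclass_sums.tsv")
    manifest.add("lipid_quant",
                 {"matrix": outdir / "lipids_normalized_log2.tsv",
                  "subclass": outdir / "lipid_subclass_sums.tsv"},
                 n_rows=len(lipid_log2.data))
    results["lipids_log2"] = lipid_log2
    results["lipid_subclass"] = subclass

    # -- stage 6: differential statistics -----------------------------------
    diff_tables = {}
    matrices = {"global": proteins,
                "redox": site_matrices["redox"][1],
                "phospho": site_matrices["phospho"][1],
                "lipid": lipid_log2}
    for name, matrix in matrices.items():
        per_time = []
        for t in (24, 48, 72):
            model = diff_stats.ModeratedTTest(matrix, f"low_{t}h", f"high_{t}h",
                                              moderate=moderate, min_reps=cfg.min_bio_reps)
            per_time.append(model.fit().table)
        diff_tables[name] = pd.concat(per_time, ignore_index=True)
        diff_tables[name].to_csv(outdir / f"diff_{name}.tsv", sep="\t", index=False)
    factorial = diff_stats.FactorialModel(site_matrices["redox"][1], moderate=moderate,
                                          min_reps=cfg.min_bio_reps).fit()
    factorial.table.to_csv(outdir / "diff_redox_factorial.tsv", sep="\t", index=False)
    manifest.add("diff_stats", {f"diff_{k}": outdir / f"diff_{k}.tsv" for k in diff_tables},
                 n_rows=sum(len(t) for t in diff_tables.values()))
    results["diff"] = diff_tables
    results["factorial"] = factorial

    # -- stage 7: enrichment -------------------------------------------------
    table72 = diff_tables["redox"]
    redox72 = diff_stats.DiffResults(table72[table72["contrast"] == "low_72h vs high_72h"])
    site_ids = set(redox72.table["feature_id"])
    selected_sites = enrich.kegg_input_filter(redox72, cfg)
    to_protein = lambda ids: {s.rsplit("_", 1)[0] for s in ids}
    universe = to_protein(site_ids)
    ora = (enrich.enrich_collection(to_protein(selected_sites), study.protein_sets, universe, cfg)
           if selected_sites else pd.DataFrame())
    ora.to_csv(outdir / "enrich_redox_72h.tsv", sep="\t", index=False)
    lipid72 = diff_tables["lipid"]
    lipid72 = lipid72[lipid72["contrast"] == "low_72h vs high_72h"]
    scores = pd.Series(lipid72["log2FC"].to_numpy(), index=lipid72["feature_id"])
    lsea = enrich.lsea(scores, study.lipid_sets, cfg)
    lsea.to_csv(outdir / "lsea_72h.tsv", sep="\t", index=False)
    manifest.add("enrichment", {"ora": outdir / "enrich_redox_72h.tsv",
                                "lsea": outdir / "lsea_72h.tsv"},
                 n_rows=len(ora) + len(lsea))
    results["ora"] = ora
    results["lsea"] = lsea

    # -- stage 8: redox-lipid integration ------------------------------------
    site_means = enrich.condition_means(site_matrices["redox"][1])
    subclass_log2 = global_quant.log2_transform(subclass)
    lipid_means = enrich.condition_means(subclass_log2)
    corr = enrich.correlate_sites_lipids(site_means, lipid_means)
    corr.rows.to_csv(outdir / "site_lipid_correlations.tsv", sep="\t", index=False)
    selection = enrich.select_correlated_sites(corr, factorial, cfg)
    sel_path = outdir / "integration_selected_sites.txt"
    sel_path.write_text("\n".join(sorted(selection)) + "\n")
    int_ora = (enrich.enrich_collection(to_protein(selection), study.protein_sets,
                                        to_protein(set(site_means.index)), cfg)
               if selection else pd.DataFrame())
    int_ora.to_csv(outdir / "integration_enrichment.tsv", sep="\t", index=False)
    manifest.add("integrate", {"correlations": outdir / "site_lipid_correlations.tsv",
                               "selected": sel_path,
                               "enrichment": outdir / "integration_enrichment.tsv"},
                 n_rows=len(corr.rows), n_dropped=len(corr.omitted))
    results["correlations"] = corr
    results["selection"] = selection
    results["integration_ora"] = int_ora

    # -- descriptive outputs -------------------------------------------------
    pca = pca_scores(proteins)
    pca.to_csv(outdir / "global_pca_scores.tsv", sep="\t")
    samp_corr = sample_correlation(proteins)
    samp_corr.to_csv(outdir / "global_sample_correlation.tsv", sep="\t")
    manifest.add("descriptive", {"pca": outdir / "global_pca_scores.tsv",
                                 "correlation": outdir / "global_sample_correlation.tsv"},
                 n_rows=len(pca))

    manifest.write(outdir / "manifest.json")
    return manifest, results
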
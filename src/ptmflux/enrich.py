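"""Set enrichment and the redox-lipid integration.

Over-representation analysis (ORA) uses the exact hypergeometric upper tail
within a declared universe; the lipid-set analysis (LSEA) is a rank test of
set members' log2 fold changes against non-members.  Integration correlates
per-condition mean cysteine-site abundances with lipid-subclass sums and
selects sites by correlation and fold-change thresholds for a final ORA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceMatrix
from .diff_stats import DiffResults, bh_adjust
from .io import FilterConfig, SetCollection

__all__ = [
    "EnrichmentResult",
    "CorrelationResult",
    "ora_hypergeometric",
    "enrich_collection",
    "rank_set_test",
    "lsea",
    "condition_means",
    "correlate_sites_lipids",
    "select_correlated_sites",
    "kegg_input_filter",
    "msea_input_filter",
    "storey_qvalues",
]

log = logging.getLogger(__name__)

EXACT_RANK_TEST_MAX = 12  # total features at or below which the rank test is exact


@dataclass
class EnrichmentResult:
    set_name: str
    overlap_k: int
    set_size_K: int
    selected_n: int
    universe_N: int
    p: float
    adj_p: float = np.nan
    q: float = np.nan
    direction: str = "two-sided"

    def __post_init__(self):
        if self.overlap_k > min(self.set_size_K, self.selected_n):
            raise ValueError("overlap cannot exceed set or selection size")


@dataclass
class CorrelationResult:
    """Pearson correlations of site trajectories against lipid-subclass
    trajectories over the condition grid (r reported only with >= 3
    conditions); sites with degenerate (zero-variance) trajectories are
    listed in ``omitted``."""

    rows: pd.DataFrame  # columns: site, target, pearson_r, n_conditions
    omitted: list[str]

    def pivot(self) -> pd.DataFrame:
        return self.rows.pivot(index="site", columns="target", values="pearson_r")


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------

def ora_hypergeometric(selected: set[str], members: set[str], universe: set[str],
                       set_name: str = "") -> EnrichmentResult:
    """Exact hypergeometric upper-tail test P(X >= k) of an id selection
    against one set, both restricted to the universe."""
    if not universe or not selected:
        raise ValueError("universe and selection must be non-empty")
    if not selected <= universe:
        raise ValueError("selection must be a subset of the universe")
    members = set(members) & set(universe)
    N, K, n = len(universe), len(members), len(selected)
    k = len(selected & members)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(set_name=set_name, overlap_k=k, set_size_K=K,
                            selected_n=n, universe_N=N, p=min(p, 1.0))


def enrich_collection(selected: set[str], collection: SetCollection, universe: set[str],
                      cfg: FilterConfig | None = None) -> pd.DataFrame:
    """ORA of a selection against every set in a collection.

    Sets are restricted to the universe and must keep >= ``min_set_size``
    members.  BH-adjusted p and Storey q-values are added; the reported flag
    applies the joint ``adj_p <= adj_p_max`` and ``q <= q_max_enrich`` rule.
    """
    cfg = cfg or FilterConfig()
    restricted = collection.restricted(set(universe), min_size=cfg.min_set_size)
    results = [
        ora_hypergeometric(selected, members, universe, set_name=name)
        for name, (_, members) in sorted(restricted.sets.items())
    ]
    if not results:
        return pd.DataFrame(columns=["set_name", "overlap_k", "set_size_K", "selected_n",
                                     "universe_N", "p", "adj_p", "q", "direction", "reported"])
    df = pd.DataFrame([r.__dict__ for r in results])
    df["adj_p"] = bh_adjust(df["p"])
    df["q"] = storey_qvalues(df["p"].to_numpy())
    df["reported"] = (df["adj_p"] <= cfg.adj_p_max) & (df["q"] <= cfg.q_max_enrich)
    return df.sort_values("p", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Rank-based set test (LSEA)
# ---------------------------------------------------------------------------

def rank_set_test(scores: dict[str, float] | pd.Series, members: set[str],
                  set_name: str = "") -> EnrichmentResult:
    """Two-sided rank-sum test of set members' log2FC ranks vs non-members.

    Exact null enumeration is used when the total number of scored features
    is <= 12; otherwise the normal approximation with continuity correction.
    Fully tied scores give p = 1.
    """
    scores = pd.Series(scores, dtype=float).dropna()
    in_set = scores.index.isin(set(members))
    x, y = scores[in_set].to_numpy(), scores[~in_set].to_numpy()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("set and complement must both have scored members")
    if np.all(scores.to_numpy() == scores.iloc[0]):
        p, direction = 1.0, "two-sided"
    else:
        has_ties = len(np.unique(scores.to_numpy())) < len(scores)
        method = "exact" if (len(scores) <= EXACT_RANK_TEST_MAX and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                                 use_continuity=True)
        p = float(res.pvalue)
        ranks = stats.rankdata(scores.to_numpy())
        delta = np.median(ranks[in_set]) - np.median(ranks[~in_set])
        direction = "up" if delta > 0 else ("down" if delta < 0 else "two-sided")
    return EnrichmentResult(set_name=set_name, overlap_k=int(in_set.sum()),
                            set_size_K=int(in_set.sum()), selected_n=len(scores),
                            universe_N=len(scores), p=min(p, 1.0), direction=direction)


def lsea(scores: dict[str, float] | pd.Series, collection: SetCollection,
         cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Rank-based lipid set enrichment over a log2FC ranking."""
    cfg = cfg or FilterConfig()
    scores = pd.Series(scores, dtype=float).dropna()
    restricted = collection.restricted(set(scores.index), min_size=cfg.min_set_size)
    rows = []
    for name, (_, members) in sorted(restricted.sets.items()):
        if len(scores) - len(members & set(scores.index)) == 0:
            continue  # set covers the whole ranking; no complement to test
        rows.append(rank_set_test(scores, members, set_name=name).__dict__)
    if not rows:
        return pd.DataFrame(columns=["set_name", "overlap_k", "set_size_K", "selected_n",
                                     "universe_N", "p", "adj_p", "q", "direction", "reported"])
    df = pd.DataFrame(rows)
    df["adj_p"] = bh_adjust(df["p"])
    df["q"] = storey_qvalues(df["p"].to_numpy())
    df["reported"] = (df["adj_p"] <= cfg.adj_p_max) & (df["q"] <= cfg.q_max_enrich)
    return df.sort_values("p", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Integration: condition means, correlation, selection
# ---------------------------------------------------------------------------

def condition_means(m: AbundanceMatrix) -> pd.DataFrame:
    """Arithmetic mean over a condition's replicate channels (missing
    replicates skipped), feature x condition over the 2x3 grid."""
    out = {}
    for cond in m.conditions:
        cols = m.condition_columns(cond)
        if len(cols):
            out[cond] = m.data[cols].mean(axis=1)
    return pd.DataFrame(out)


def correlate_sites_lipids(site_means: pd.DataFrame, lipid_means: pd.DataFrame) -> CorrelationResult:
    """Pearson r of every (site, lipid subclass) pair over the shared
    condition means; degenerate zero-variance trajectories are omitted."""
    shared = [c for c in site_means.columns if c in lipid_means.columns]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared conditions for correlations")
    S = site_means[shared].to_numpy(dtype=float)
    L = lipid_means[shared].to_numpy(dtype=float)
    omitted = []
    rows = []
    s_sd = S.std(axis=1)
    l_sd = L.std(axis=1)
    s_ok = ~np.isnan(S).any(axis=1) & (s_sd > 0)
    omitted = [str(s) for s, o in zip(site_means.index, s_ok) if not o]
    Sz = (S[s_ok] - S[s_ok].mean(axis=1, keepdims=True)) / s_sd[s_ok][:, None]
    for j, target in enumerate(lipid_means.index):
        if np.isnan(L[j]).any() or l_sd[j] == 0:
            log.info("correlate_sites_lipids: target %s omitted (degenerate)", target)
            continue
        lz = (L[j] - L[j].mean()) / l_sd[j]
        r = (Sz * lz[None, :]).mean(axis=1)
        for site, rv in zip(np.asarray(site_means.index)[s_ok], r):
            rows.append((site, target, float(np.clip(rv, -1.0, 1.0)), len(shared)))
    return CorrelationResult(
        rows=pd.DataFrame(rows, columns=["site", "target", "pearson_r", "n_conditions"]),
        omitted=omitted,
    )


def select_correlated_sites(corr: CorrelationResult, diff: DiffResults,
                            cfg: FilterConfig | None = None,
                            targets: tuple[str, str] = ("TG", "DG"),
                            mode: str = "all") -> set[str]:
    """Sites whose trajectories track the storage-lipid subclasses.

    Default rule: Pearson r > ``pearson_min`` against *both* TG and DG
    (``mode="any"`` relaxes to either) and |log2FC| >= ``lfc_min_ptm`` for
    the nitrogen coefficient of the factorial fit.
    """
    cfg = cfg or FilterConfig()
    piv = corr.pivot()
    masks = [(piv[t] > cfg.pearson_min) for t in targets if t in piv.columns]
    if not masks:
        return set()
    combined = masks[0]
    for mask in masks[1:]:
        combined = (combined & mask) if mode == "all" else (combined | mask)
    correlated = set(piv.index[combined.fillna(False)])
    nit = diff.table[diff.table["contrast"] == "Nitrogen"]
    strong = set(nit.loc[nit["log2FC"].abs() >= cfg.lfc_min_ptm, "feature_id"])
    return correlated & strong


def kegg_input_filter(diff: DiffResults, cfg: FilterConfig | None = None) -> set[str]:
    """Ids entering KEGG ORA: adj p <= 0.05 and |log2FC| >= 1 (inclusive)."""
    cfg = cfg or FilterConfig()
    sig = diff.significant(cfg.adj_p_max, cfg.lfc_min_kegg_input)
    return set(sig["feature_id"])


def msea_input_filter(diff: DiffResults, cfg: FilterConfig | None = None) -> set[str]:
    """Ids entering metabolite-set ORA: adj p <= 0.05 and |log2FC| >= 4."""
    cfg = cfg or FilterConfig()
    sig = diff.significant(cfg.adj_p_max, cfg.lfc_min_msea)
    return set(sig["feature_id"])


def storey_qvalues(p: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with fixed lambda: pi0 = min(1, #{p > lam} / ((1-lam) m)),
    then the BH step-up scaled by pi0."""
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p
    pi0 = min(1.0, float((p > lam).sum()) / ((1.0 - lam) * m))
    pi0 = max(pi0, 1.0 / m)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, pi0 * m * p[i] / rank)
        q[i] = prev
    return q
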
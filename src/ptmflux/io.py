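"""Reading, validating and writing the study's external tables.

Covers TMT plex-design tables (TSV), PSM-level reporter-intensity tables
(TSV), lipid peak-height tables (CSV), GMT set collections, and the global
filter-threshold configuration (YAML).  All readers validate invariants and
report *every* violation found, not just the first.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "SiteKey",
    "FilterConfig",
    "PlexDesign",
    "PSMTable",
    "LipidTable",
    "SetCollection",
    "ValidationError",
    "parse_site_key",
    "read_design",
    "write_design",
    "read_psm_table",
    "write_psm_table",
    "read_lipid_table",
    "write_lipid_table",
    "read_gmt",
    "write_gmt",
    "read_filter_config",
]

NITROGEN_LEVELS = ("high", "low", "none")
ASSAYS = ("global", "redox", "phospho")
CHANNEL_CLASSES = ("sample", "total_thiol_pool", "bridge", "empty")
TIMEPOINTS_H = (24, 48, 72)

DESIGN_COLUMNS = [
    "plex_id",
    "channel_label",
    "sample_id",
    "nitrogen",
    "timepoint_h",
    "replicate",
    "assay",
    "channel_class",
    "batch",
]

PSM_META_COLUMNS = ["plex_id", "peptide", "protein_id", "site_keys", "fdr_pass"]


class ValidationError(ValueError):
    """Raised with the complete list of violations found in an input table."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("input validation failed:\n" + "\n".join(f"- {p}" for p in self.problems))


# ---------------------------------------------------------------------------
# Site keys
# ---------------------------------------------------------------------------

_RESIDUE_RE = re.compile(r"^([CSTY])(\d+)$")


@dataclass(frozen=True, order=True)
class SiteKey:
    """A PTM site on a protein: one residue, or a composite when localization
    is ambiguous (e.g. ``S512;T513`` on one peptide).

    The canonical text form is ``<protein>_<AA><pos>[;<AA><pos>...]`` with
    1-based positions, and is bijective with the fields.
    """

    protein_id: str
    residues: tuple[tuple[str, int], ...]

    def __post_init__(self):
        if not self.residues:
            raise ValueError("SiteKey needs at least one residue")
        positions = [p for _, p in self.residues]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError(f"residue positions must be strictly increasing: {positions}")
        for aa, pos in self.residues:
            if aa not in "CSTY" or pos < 1:
                raise ValueError(f"invalid residue ({aa}, {pos})")

    @property
    def ambiguity(self) -> bool:
        return len(self.residues) > 1

    @property
    def text(self) -> str:
        return f"{self.protein_id}_" + ";".join(f"{aa}{pos}" for aa, pos in self.residues)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text


def parse_site_key(text: str) -> SiteKey:
    """Parse the canonical site-key grammar ``<protein>_<AA><pos>[;...]``.

    Protein identifiers may themselves contain underscores (e.g. ``RT_123``);
    the residue block is the final underscore-delimited token.
    """
    protein, _, res_block = text.rpartition("_")
    if not protein or not res_block:
        raise ValueError(f"malformed site key {text!r}")
    residues = []
    for token in res_block.split(";"):
        m = _RESIDUE_RE.match(token)
        if m is None:
            raise ValueError(f"malformed residue {token!r} in site key {text!r}")
        residues.append((m.group(1), int(m.group(2))))
    return SiteKey(protein_id=protein, residues=tuple(residues))


# ---------------------------------------------------------------------------
# Filter thresholds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterConfig:
    """Global filter thresholds used across differential and enrichment steps.

    Defaults mirror the study-wide cutoffs: BH-adjusted p <= 0.05 throughout;
    |log2FC| >= 0.8 for PTM-site calls, >= 1 for the KEGG over-representation
    input, >= 4 for the metabolite-set (MSEA) input; Pearson r > 0.80 for the
    redox-lipid integration; q <= 0.2 for reported enrichments; features seen
    in >= 2 biological replicates; sets with >= 2 members.
    """

    adj_p_max: float = 0.05
    lfc_min_ptm: float = 0.8
    lfc_min_kegg_input: float = 1.0
    lfc_min_msea: float = 4.0
    pearson_min: float = 0.80
    q_max_enrich: float = 0.2
    min_bio_reps: int = 2
    min_set_size: int = 2

    def __post_init__(self):
        problems = []
        for f in fields(self):
            v = getattr(self, f.name)
            if v <= 0:
                problems.append(f"{f.name} must be positive, got {v}")
        for name in ("adj_p_max", "q_max_enrich"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                problems.append(f"{name} must lie in (0, 1], got {v}")
        if problems:
            raise ValidationError(problems)


def read_filter_config(path: str | Path) -> FilterConfig:
    """Load FilterConfig overrides from a YAML key-value file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(FilterConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError([f"unknown filter setting {k!r}" for k in sorted(unknown)])
    return FilterConfig(**data)


# ---------------------------------------------------------------------------
# Plex designs
# ---------------------------------------------------------------------------

@dataclass
class PlexDesign:
    """Channel-to-sample metadata for one TMT plex.

    ``rows`` holds one record per channel with columns ``channel_label,
    sample_id, nitrogen, timepoint_h, replicate, assay, channel_class,
    batch``.  Empty channels carry no sample and never enter quantitative
    operations; redox plexes must contain pooled total-thiol reference
    channels; bridge channels are 24 h technical replicates shared across
    plexes for batch alignment.
    """

    plex_id: str
    rows: pd.DataFrame

    def __post_init__(self):
        self.rows = self.rows.reset_index(drop=True)

    @property
    def assay(self) -> str:
        return str(self.rows["assay"].iloc[0])

    @property
    def batch(self) -> str:
        return str(self.rows["batch"].iloc[0])

    def channels(self, classes: Iterable[str] | None = None) -> pd.DataFrame:
        """Rows restricted to the given channel classes (default: all
        quantitative, i.e. everything but ``empty``)."""
        if classes is None:
            classes = ("sample", "bridge", "total_thiol_pool")
        return self.rows[self.rows["channel_class"].isin(tuple(classes))]

    def condition_of(self, channel_label: str) -> str | None:
        row = self.rows[self.rows["channel_label"] == channel_label].iloc[0]
        return condition_label(row["nitrogen"], row["timepoint_h"])


def condition_label(nitrogen, timepoint_h) -> str | None:
    """Condition key ``"<nitrogen>_<hours>h"`` for a sample channel, or None
    for reference/empty channels that do not belong to the 2x3 grid."""
    if pd.isna(nitrogen) or nitrogen in ("none", "", None) or pd.isna(timepoint_h):
        return None
    return f"{nitrogen}_{int(timepoint_h)}h"


def validate_designs(designs: list[PlexDesign]) -> None:
    problems: list[str] = []
    for d in designs:
        labels = d.rows["channel_label"]
        dup = labels[labels.duplicated()].unique().tolist()
        if dup:
            problems.append(f"plex {d.plex_id}: duplicate channel labels {dup}")
        for _, r in d.rows.iterrows():
            cls = r["channel_class"]
            if cls not in CHANNEL_CLASSES:
                problems.append(f"plex {d.plex_id} channel {r['channel_label']}: unknown channel_class {cls!r}")
            if cls == "empty" and isinstance(r["sample_id"], str) and r["sample_id"]:
                problems.append(
                    f"plex {d.plex_id} channel {r['channel_label']}: empty channel carries sample_id {r['sample_id']!r}"
                )
            if cls in ("sample", "bridge") and not (isinstance(r["sample_id"], str) and r["sample_id"]):
                problems.append(f"plex {d.plex_id} channel {r['channel_label']}: {cls} channel lacks a sample_id")
            if r["nitrogen"] not in NITROGEN_LEVELS and not pd.isna(r["nitrogen"]):
                problems.append(f"plex {d.plex_id} channel {r['channel_label']}: bad nitrogen {r['nitrogen']!r}")
            if not pd.isna(r["timepoint_h"]) and int(r["timepoint_h"]) not in TIMEPOINTS_H:
                problems.append(
                    f"plex {d.plex_id} channel {r['channel_label']}: timepoint_h {r['timepoint_h']} not in {TIMEPOINTS_H}"
                )
            if r["assay"] not in ASSAYS:
                problems.append(f"plex {d.plex_id} channel {r['channel_label']}: unknown assay {r['assay']!r}")
        if d.assay == "redox" and not (d.rows["channel_class"] == "total_thiol_pool").any():
            problems.append(f"plex {d.plex_id}: redox plex has no total_thiol_pool channel")

    # bridge channels must recur across plexes with identical sample ids
    bridge_plexes: dict[str, set[str]] = {}
    for d in designs:
        for sid in d.rows.loc[d.rows["channel_class"] == "bridge", "sample_id"]:
            bridge_plexes.setdefault(sid, set()).add(d.plex_id)
    for sid, plexes in bridge_plexes.items():
        if len(plexes) < 2:
            problems.append(f"bridge sample {sid!r} appears in only one plex ({sorted(plexes)})")

    if problems:
        raise ValidationError(problems)


def read_design(path: str | Path) -> list[PlexDesign]:
    df = pd.read_csv(path, sep="\t", dtype={"plex_id": str, "channel_label": str, "batch": str})
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError([f"design file missing required column {c!r}" for c in missing])
    df["timepoint_h"] = pd.to_numeric(df["timepoint_h"], errors="coerce").astype("Int64")
    df["replicate"] = pd.to_numeric(df["replicate"], errors="coerce").astype("Int64")
    df["sample_id"] = df["sample_id"].fillna("")
    designs = [
        PlexDesign(plex_id=str(pid), rows=g[DESIGN_COLUMNS[1:]].copy())
        for pid, g in df.groupby("plex_id", sort=False)
    ]
    validate_designs(designs)
    return designs


def write_design(designs: list[PlexDesign], path: str | Path) -> None:
    parts = []
    for d in designs:
        block = d.rows.copy()
        block.insert(0, "plex_id", d.plex_id)
        parts.append(block[DESIGN_COLUMNS])
    pd.concat(parts, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

@dataclass
class PSMTable:
    """Peptide-spectrum matches with per-channel linear reporter intensities.

    ``rows`` has the metadata columns plus one intensity column per channel
    label; intensities are linear-scale, missing values are NaN (never 0).
    ``site_keys`` is a ``|``-separated list of canonical site-key strings
    (empty for global-only peptides).
    """

    rows: pd.DataFrame
    channel_labels: list[str]

    def __len__(self) -> int:
        return len(self.rows)

    def site_keys_of(self, idx) -> list[SiteKey]:
        raw = self.rows.loc[idx, "site_keys"]
        if not isinstance(raw, str) or not raw:
            return []
        return [parse_site_key(t) for t in raw.split("|")]


def read_psm_table(path: str | Path, designs: list[PlexDesign], fdr_only: bool = True) -> PSMTable:
    """Read a PSM reporter-intensity TSV and check it against the design.

    With ``fdr_only`` (the default), rows failing the 1% FDR flag are
    dropped, mirroring the identification filter applied upstream.
    """
    df = pd.read_csv(path, sep="\t", dtype={"plex_id": str, "peptide": str, "protein_id": str})
    problems = []
    missing = [c for c in PSM_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError([f"PSM table missing required column {c!r}" for c in missing])
    design_channels = {
        (d.plex_id, lab) for d in designs for lab in d.rows["channel_label"]
    }
    design_plexes = {d.plex_id for d in designs}
    intensity_cols = [c for c in df.columns if c not in PSM_META_COLUMNS]
    design_labels = {lab for _, lab in design_channels}
    for c in intensity_cols:
        if c not in design_labels:
            problems.append(f"intensity column {c!r} matches no design channel")
    for pid in df["plex_id"].unique():
        if pid not in design_plexes:
            problems.append(f"PSM rows reference unknown plex {pid!r}")
    vals = df[intensity_cols].apply(pd.to_numeric, errors="coerce")
    neg = vals < 0
    if neg.any().any():
        for col in intensity_cols:
            for i in df.index[neg[col].fillna(False)]:
                problems.append(f"negative intensity {vals.at[i, col]} in row {i}, channel {col!r}")
    for i, raw in df["site_keys"].items():
        if isinstance(raw, str) and raw:
            for token in raw.split("|"):
                try:
                    parse_site_key(token)
                except ValueError as e:
                    problems.append(str(e))
    if problems:
        raise ValidationError(problems)
    df[intensity_cols] = vals
    df["site_keys"] = df["site_keys"].fillna("")
    df["fdr_pass"] = df["fdr_pass"].astype(bool)
    n_total = len(df)
    if fdr_only:
        df = df[df["fdr_pass"]].reset_index(drop=True)
    table = PSMTable(rows=df, channel_labels=intensity_cols)
    import logging

    logging.getLogger(__name__).info(
        "read %d PSM rows from %s (%d before FDR filter)", len(df), path, n_total
    )
    return table


def write_psm_table(psm: PSMTable, path: str | Path) -> None:
    psm.rows[PSM_META_COLUMNS + psm.channel_labels].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Lipid tables
# ---------------------------------------------------------------------------

@dataclass
class LipidTable:
    """Lipid species x sample peak heights with class/subclass annotation.

    Blank and zero cells are recorded as missing at load time (the study's
    "0 -> missing" rule applies to lipid input only).
    """

    rows: pd.DataFrame  # columns: lipid_id, class, subclass, then samples
    sample_ids: list[str]

    def intensities(self) -> pd.DataFrame:
        return self.rows.set_index("lipid_id")[self.sample_ids]


def read_lipid_table(path: str | Path) -> LipidTable:
    df = pd.read_csv(path, dtype={"lipid_id": str, "class": str, "subclass": str})
    problems = []
    for c in ("lipid_id", "class", "subclass"):
        if c not in df.columns:
            problems.append(f"lipid table missing required column {c!r}")
    if problems:
        raise ValidationError(problems)
    dup = df["lipid_id"][df["lipid_id"].duplicated()].unique().tolist()
    if dup:
        problems.append(f"duplicate lipid_id values {dup}")
    if df["class"].isna().any() or df["subclass"].isna().any():
        problems.append("every lipid needs class and subclass labels")
    if problems:
        raise ValidationError(problems)
    sample_ids = [c for c in df.columns if c not in ("lipid_id", "class", "subclass")]
    vals = df[sample_ids].apply(pd.to_numeric, errors="coerce")
    vals = vals.where(vals > 0)  # blanks and zeros -> missing
    df = df.copy()
    df[sample_ids] = vals
    return LipidTable(rows=df, sample_ids=sample_ids)


def write_lipid_table(table: LipidTable, path: str | Path) -> None:
    table.rows.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GMT set collections
# ---------------------------------------------------------------------------

@dataclass
class SetCollection:
    """Named feature sets (``name -> (description, member ids)``), read from
    the standard GMT format; membership is intersected with a declared
    universe at use time."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def restricted(self, universe: set[str], min_size: int = 1) -> "SetCollection":
        out = {}
        for name, (desc, members) in self.sets.items():
            kept = frozenset(members & universe)
            if len(kept) >= min_size:
                out[name] = (desc, kept)
        return SetCollection(out)


def read_gmt(path: str | Path) -> SetCollection:
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    problems = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                problems.append(f"GMT line {lineno}: fewer than one member ({line!r})")
                continue
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if not members:
                problems.append(f"GMT line {lineno}: set {name!r} has no members")
                continue
            sets[name] = (desc, frozenset(members))
    if problems:
        raise ValidationError(problems)
    return SetCollection(sets)


def write_gmt(collection: SetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")
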
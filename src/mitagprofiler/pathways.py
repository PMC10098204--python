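"""Taxon-resolved pathway-completeness calling from ORF annotations.

Annotation rows (one per ORF: gene symbol, KO id, percent identity of the
best protein hit, taxon assignment, read support) are filtered at an
identity cut-off (default 60%), then each pathway's completeness is the
fraction of its required genes detected at least once.  A pathway is
called present when completeness reaches the presence threshold (default
80%).  Detection is binary per distinct gene — multiple ORFs for one gene
count once toward completeness but sum toward read support.

A small editable pathway bundle ships with the package covering the
chemolithoautotrophic repertoire relevant to anoxic sulphidic systems:
carbon fixation (reductive citric acid cycle, Wood–Ljungdahl), sulphur
and nitrogen cycling, hydrogenases, arsenate reduction, fumarate
respiration and carboxydotrophy.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ("orf_id", "gene_symbol", "ko_id",
                      "percent_identity", "taxon_id", "read_support")
COMMUNITY = "community"


@dataclass(frozen=True)
class PathwayDefinition:
    pathway_id: str
    name: str
    required_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.required_genes:
            raise ValueError(f"{self.pathway_id}: required_genes must be non-empty")


@dataclass(frozen=True)
class PathwayCall:
    taxon_id: str
    pathway_id: str
    detected_genes: frozenset[str]
    completeness: float
    present: bool
    read_support: int


def load_pathway_bundle(path: str | Path | None = None) -> list[PathwayDefinition]:
    """Load pathway definitions from TSV (pathway_id, name, required_genes
    comma-separated); defaults to the packaged bundle."""
    if path is None:
        source = resources.files("mitagprofiler").joinpath("data/pathways.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return [
        PathwayDefinition(
            row.pathway_id, row.name,
            frozenset(g.strip() for g in str(row.required_genes).split(",") if g.strip()),
        )
        for row in df.itertuples()
    ]


def validate_annotations(rows: pd.DataFrame) -> pd.DataFrame:
    missing = set(ANNOTATION_COLUMNS) - set(rows.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    ident = rows["percent_identity"]
    if ((ident < 0) | (ident > 1)).any():
        raise ValueError("percent_identity must be a fraction in [0, 1]")
    if (rows["read_support"] < 0).any():
        raise ValueError("read_support must be non-negative")
    return rows


def filter_annotations(rows: pd.DataFrame, min_identity: float = 0.60) -> pd.DataFrame:
    """Keep rows with percent identity ≥ the cut-off (inclusive), stable order."""
    validate_annotations(rows)
    return rows[rows["percent_identity"] >= min_identity].copy()


def pathway_completeness(
    rows: pd.DataFrame,
    pathways: Sequence[PathwayDefinition],
    presence_threshold: float = 0.80,
    level: str = "taxon",
) -> list[PathwayCall]:
    """Per-taxon (or pooled community) completeness and presence calls.

    ``level='taxon'`` groups rows by taxon assignment; ``'community'``
    pools everything into one grouping unit.  Presence is inclusive at
    the threshold.
    """
    if level not in ("taxon", "community"):
        raise ValueError(f"level must be 'taxon' or 'community', got {level!r}")
    validate_annotations(rows)
    if level == "community":
        groups = {COMMUNITY: rows}
    else:
        groups = {str(t): g for t, g in rows.groupby("taxon_id", sort=True)}

    calls: list[PathwayCall] = []
    for unit, group in groups.items():
        genes_present = set(group["gene_symbol"])
        support_by_gene = group.groupby("gene_symbol")["read_support"].sum()
        for pw in pathways:
            detected = frozenset(g for g in pw.required_genes if g in genes_present)
            completeness = len(detected) / len(pw.required_genes)
            support = int(support_by_gene.reindex(sorted(detected)).fillna(0).sum())
            calls.append(PathwayCall(
                taxon_id=unit,
                pathway_id=pw.pathway_id,
                detected_genes=detected,
                completeness=completeness,
                present=completeness >= presence_threshold,
                read_support=support,
            ))
    return calls


def taxon_function_matrix(
    calls: Iterable[PathwayCall],
    rows: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tidy taxon × pathway table with completeness, read support and
    log-scaled support (log10(1 + n), the radius scale of a bubble plot)."""
    records = [{
        "taxon_id": c.taxon_id,
        "pathway_id": c.pathway_id,
        "completeness": c.completeness,
        "present": c.present,
        "read_support": c.read_support,
        "log10_read_support": float(np.log10(1 + c.read_support)),
    } for c in calls]
    df = pd.DataFrame(records, columns=["taxon_id", "pathway_id", "completeness",
                                        "present", "read_support", "log10_read_support"])
    return df.sort_values(["taxon_id", "pathway_id"], ignore_index=True)


def call_pathways(
    rows: pd.DataFrame,
    pathways: Sequence[PathwayDefinition],
    min_identity: float = 0.60,
    presence_threshold: float = 0.80,
) -> pd.DataFrame:
    """Filter, call per-taxon and community-level pathways, return the matrix."""
    kept = filter_annotations(rows, min_identity)
    calls = pathway_completeness(kept, pathways, presence_threshold, level="taxon")
    calls += pathway_completeness(kept, pathways, presence_threshold, level="community")
    return taxon_function_matrix(calls, kept)
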
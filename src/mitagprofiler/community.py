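"""Community profiling from recruitment counts.

Raw per-gene read counts are biased by gene length (longer genes emit
more fragments) and by rDNA operon copy number (a 12-copy genome emits
twelve times the reads per cell).  ``normalise`` divides both out:

    weight_t = Σ_g  count_{t,g} / (length_{t,g} × copies_t)

and relative abundances are the weights renormalised to one.  Shannon
diversity (natural log) and Pielou evenness summarise the profile.

``collapse_taxonomy`` implements abundance-based tree collapsing: leaves
are sorted by decreasing abundance, the minimal prefix holding ≥95% of
the total is flagged significant, and every remaining leaf's abundance is
folded into the significant leaf sharing its deepest common ancestor.
The pass repeats until no leaf is insignificant, making the operation
idempotent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .references import RANKS, OperonReference


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def estimate_copy_number(lineage: Sequence[str],
                         copy_table: Mapping[str, float]) -> int:
    """Copy number from the mean at the most specific rank with an entry.

    ``copy_table`` maps taxon names (any rank) to mean operon copies, as
    compiled from a copy-number database; the lineage is walked genus →
    domain and the first present name wins, its mean rounded half-up.
    """
    if not lineage:
        raise ValueError("empty lineage")
    for name in reversed(list(lineage)):
        if name in copy_table:
            return round_half_up(float(copy_table[name]))
    raise KeyError(f"no copy-table entry at any rank of {list(lineage)!r}")


@dataclass
class AbundanceProfile:
    sample_id: str
    raw_counts: dict[str, dict[str, int]]
    normalised_weight: dict[str, float]
    relative_abundance: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        taxa = sorted(self.relative_abundance)
        return pd.DataFrame({
            "taxon_id": taxa,
            "raw_count": [sum(self.raw_counts.get(t, {}).values()) for t in taxa],
            "normalised_weight": [self.normalised_weight[t] for t in taxa],
            "relative_abundance": [self.relative_abundance[t] for t in taxa],
        })


def normalise(
    raw_counts: Mapping[str, Mapping[str, int]],
    refs: Sequence[OperonReference],
    copy_correction: bool = True,
    sample_id: str = "sample",
) -> AbundanceProfile:
    """Length- and copy-number-normalised relative abundances.

    ``copy_correction=False`` keeps the length normalisation only, which
    exposes how strongly copy number distorts the raw profile.
    """
    by_id = {r.taxon_id: r for r in refs}
    weights: dict[str, float] = {}
    for taxon, genes in raw_counts.items():
        if taxon not in by_id:
            raise ValueError(f"counts for unknown taxon {taxon!r}")
        ref = by_id[taxon]
        copies = ref.copy_number if copy_correction else 1
        if copies < 1:
            raise ValueError(f"{taxon}: copy number must be >= 1")
        w = 0.0
        for gene, count in genes.items():
            length = len(ref.genes.get(gene, ""))
            if length == 0:
                raise ValueError(f"{taxon}/{gene}: zero-length reference gene")
            w += count / (length * copies)
        weights[taxon] = w
    total = sum(weights.values())
    rel = {t: (w / total if total > 0 else 0.0) for t, w in weights.items()}
    return AbundanceProfile(sample_id, {t: dict(g) for t, g in raw_counts.items()},
                            weights, rel)


@dataclass(frozen=True)
class DiversityStats:
    shannon_H: float
    richness_S: int
    pielou_J: float | None


def diversity(profile: AbundanceProfile | Mapping[str, float] | Sequence[float]
              ) -> DiversityStats:
    """Shannon H (nats) over non-zero abundances, richness, Pielou J = H/ln S."""
    if isinstance(profile, AbundanceProfile):
        values = np.array(list(profile.relative_abundance.values()), dtype=float)
    elif isinstance(profile, Mapping):
        values = np.array(list(profile.values()), dtype=float)
    else:
        values = np.asarray(profile, dtype=float)
    if values.size == 0 or values.sum() <= 0:
        raise ValueError("diversity needs at least one non-zero abundance")
    if (values < 0).any():
        raise ValueError("abundances must be non-negative")
    p = values[values > 0]
    p = p / p.sum()
    h = float(-(p * np.log(p)).sum())
    s = int(p.size)
    j = h / math.log(s) if s >= 2 else None
    return DiversityStats(h, s, j)


# ---------------------------------------------------------------------------
# taxonomy tree + collapsing

@dataclass
class TaxLeaf:
    """A tree leaf: full lineage path (root rank first) and its abundance."""

    path: tuple[str, ...]
    abundance: float

    @property
    def name(self) -> str:
        return self.path[-1]

    @property
    def depth(self) -> int:
        return len(self.path)

    @property
    def rank(self) -> str:
        return RANKS[self.depth - 1] if self.depth <= len(RANKS) else "leaf"


@dataclass
class TaxonomyTree:
    """Rank-labelled lineage tree stored as its leaf set.

    The internal structure is implied by shared lineage prefixes, which is
    exactly what the collapsing algorithm consumes (depth of the common
    ancestor = length of the shared prefix).
    """

    leaves: list[TaxLeaf] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for leaf in self.leaves:
            if leaf.path in seen:
                raise ValueError(f"duplicate leaf path {leaf.path}")
            seen.add(leaf.path)
            if not np.isfinite(leaf.abundance) or leaf.abundance < 0:
                raise ValueError(f"{leaf.path}: abundance must be finite and >= 0")

    @classmethod
    def from_records(cls, records: Iterable[tuple[Sequence[str], float]]) -> "TaxonomyTree":
        return cls([TaxLeaf(tuple(path), float(ab)) for path, ab in records])

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyTree":
        df = pd.read_csv(path, sep="\t", dtype={"lineage": str})
        return cls.from_records(
            (tuple(row.lineage.split(";")), row.abundance) for row in df.itertuples()
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame({
            "lineage": [";".join(l.path) for l in self.leaves],
            "abundance": [l.abundance for l in self.leaves],
        }).to_csv(path, sep="\t", index=False)

    def total(self) -> float:
        return sum(l.abundance for l in self.leaves)

    def copy(self) -> "TaxonomyTree":
        return TaxonomyTree([TaxLeaf(l.path, l.abundance) for l in self.leaves])

    def to_newick(self) -> str:
        """Newick export with abundances as leaf branch comments."""
        root: dict = {}
        for leaf in self.leaves:
            node = root
            for part in leaf.path[:-1]:
                node = node.setdefault(part, {})
            node[leaf.path[-1]] = leaf.abundance

        def render_inner(node: dict) -> str:
            parts = []
            for name, child in sorted(node.items()):
                if isinstance(child, dict):
                    parts.append(f"({render_inner(child)}){name}")
                else:
                    parts.append(f"{name}[&abundance={child:g}]")
            return ",".join(parts)

        return f"({render_inner(root)});"


@dataclass(frozen=True)
class Reassignment:
    source: tuple[str, ...]
    target: tuple[str, ...]
    abundance: float
    shared_depth: int


def _common_prefix(a: Sequence[str], b: Sequence[str]) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _collapse_pass(leaves: list[TaxLeaf], significance: float
                   ) -> tuple[list[TaxLeaf], list[Reassignment]]:
    order = sorted(leaves, key=lambda l: (-l.abundance, l.path))
    total = sum(l.abundance for l in order)
    cum = 0.0
    significant: list[TaxLeaf] = []
    insignificant: list[TaxLeaf] = []
    for leaf in order:
        if cum >= significance * total and significant:
            insignificant.append(leaf)
        else:
            significant.append(leaf)  # includes the leaf crossing the threshold
            cum += leaf.abundance
    if not insignificant:
        return order, []

    snapshot = {l.path: l.abundance for l in significant}
    merged = {l.path: l.abundance for l in significant}
    log: list[Reassignment] = []
    for leaf in insignificant:
        best = min(
            significant,
            key=lambda cand: (
                -_common_prefix(leaf.path, cand.path),  # deepest common ancestor
                cand.depth != leaf.depth,               # same rank preferred
                -snapshot[cand.path],                   # then higher abundance
                cand.path,                              # then lexicographic name
            ),
        )
        merged[best.path] += leaf.abundance
        log.append(Reassignment(leaf.path, best.path, leaf.abundance,
                                _common_prefix(leaf.path, best.path)))
    return [TaxLeaf(p, a) for p, a in merged.items()], log


def collapse_taxonomy(tree: TaxonomyTree, significance: float = 0.95
                      ) -> tuple[TaxonomyTree, list[Reassignment]]:
    """Fold low-abundance leaves into their closest significant relatives.

    Leaves are sorted by decreasing abundance; the minimal prefix whose
    cumulative share reaches ``significance`` is kept (the crossing leaf
    included).  Every other leaf is reassigned to the significant leaf
    with the deepest common ancestor — same rank preferred, ties broken
    by higher abundance, then lexicographically smaller name.  Passes
    repeat until every remaining leaf is significant, so the result is a
    fixed point: collapsing again changes nothing.  Total abundance is
    conserved exactly up to float addition.
    """
    if not tree.leaves:
        raise ValueError("cannot collapse an empty tree")
    if not 0.0 < significance <= 1.0:
        raise ValueError("significance must be in (0, 1]")
    if tree.total() <= 0:
        raise ValueError("total abundance must be positive")
    leaves = [TaxLeaf(l.path, l.abundance) for l in tree.leaves]
    log: list[Reassignment] = []
    for _ in range(len(leaves)):
        leaves, moves = _collapse_pass(leaves, significance)
        if not moves:
            break
        log.extend(moves)
    out = TaxonomyTree(sorted(leaves, key=lambda l: (-l.abundance, l.path)))
    return out, log


def tree_from_profile(profile: AbundanceProfile,
                      refs: Sequence[OperonReference]) -> TaxonomyTree:
    """Leaf per taxon at its lineage path, weighted by raw read count."""
    by_id = {r.taxon_id: r for r in refs}
    records = []
    for taxon, genes in profile.raw_counts.items():
        lineage = by_id[taxon].lineage if taxon in by_id else (taxon,)
        records.append((tuple(lineage), float(sum(genes.values()))))
    return TaxonomyTree.from_records(records)
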
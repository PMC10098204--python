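"""Mock communities with known ground truth.

Everything downstream of sequencing is testable against this module: it
emits per-taxon rDNA operon references, overlapping paired-end reads with
the copy-number bias *built in* (so normalisation has something real to
undo), and ORF annotation tables with a planned pathway completeness per
taxon.

The default community emulates a low-diversity anoxic subglacial-lake
assemblage: seven dominant genera (sulphur oxidisers, acetogens, metal and
sulphur reducers) plus a high-copy-number minor taxon, with rDNA operon
copy numbers between 1 and 12 and inter-taxon 16S identity spanning
roughly 83–99%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pathways import PathwayDefinition
from .read_prep import ReadRecord
from .references import GENE_LENGTHS, GENE_NAMES, OperonReference, check_unique_taxa

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP[a] = b

HIGH_QUALITY = 37  # constant base quality away from simulated errors
LOW_QUALITY = 8    # quality assigned (with prob. 0.5) at error positions


def _revcomp_bytes(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr[::-1]]


@dataclass(frozen=True)
class MockTaxon:
    taxon_id: str
    lineage: tuple[str, ...]
    cell_fraction: float
    operon_copy_number: int


@dataclass(frozen=True)
class MockCommunity:
    """A set of taxa with cell fractions summing to one."""

    taxa: tuple[MockTaxon, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxa", tuple(self.taxa))
        ids = [t.taxon_id for t in self.taxa]
        if len(set(ids)) != len(ids):
            raise ValueError("taxon_ids must be unique")
        total = sum(t.cell_fraction for t in self.taxa)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cell_fractions must sum to 1, got {total!r}")
        for t in self.taxa:
            if t.operon_copy_number < 1:
                raise ValueError(f"{t.taxon_id}: operon_copy_number must be >= 1")
            if not 0.0 <= t.cell_fraction <= 1.0:
                raise ValueError(f"{t.taxon_id}: cell_fraction outside [0, 1]")

    @property
    def fractions(self) -> dict[str, float]:
        return {t.taxon_id: t.cell_fraction for t in self.taxa}


@dataclass(frozen=True)
class SimulationConfig:
    """Sequencing-run parameters.

    ``depth`` is the expected number of read pairs per unit of
    (cell_fraction × copy_number × kilobase of rDNA); total library size
    scales linearly with it.  Insert sizes are truncated-normal with a
    floor at ``read_length`` so every pair overlaps and can be merged.
    """

    read_length: int = 108
    insert_mean: int = 175
    insert_sd: float = 15.0
    per_base_error_rate: float = 0.001
    depth: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 1 or self.insert_mean < self.read_length:
            raise ValueError("need read_length >= 1 and insert_mean >= read_length")
        if not self.insert_mean < 2 * self.read_length:
            raise ValueError(
                "insert_mean must be < 2*read_length for pairs to overlap and merge"
            )
        if not 0.0 <= self.per_base_error_rate < 1.0:
            raise ValueError("per_base_error_rate must be in [0, 1)")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


def _disjoint_positions(rng: np.random.Generator, length: int,
                        counts: Sequence[int]) -> list[np.ndarray]:
    """Partition random positions of [0, length) into per-taxon disjoint sets."""
    if sum(counts) > length:
        raise ValueError(
            "divergence_range too wide for this many taxa: disjoint mutation "
            f"sets need {sum(counts)} positions but the gene has {length}"
        )
    perm = rng.permutation(length)
    out, offset = [], 0
    for c in counts:
        out.append(np.sort(perm[offset:offset + c]))
        offset += c
    return out


def _mutate(rng: np.random.Generator, seq: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Substitute each position with a different random base (no indels)."""
    out = seq.copy()
    idx = np.searchsorted(_BASES, out[positions])
    shift = rng.integers(1, 4, size=len(positions))
    out[positions] = _BASES[(idx + shift) % 4]
    return out


def build_mock_operons(
    seed: int,
    n_taxa: int,
    divergence_range: tuple[float, float] = (0.83, 0.99),
    copy_numbers: Sequence[int] | None = None,
) -> list[OperonReference]:
    """Derive ``n_taxa`` operons from one random ancestor by point substitution.

    Each taxon mutates its own disjoint set of 16S positions, so the
    pairwise 16S identity of taxa *i*, *j* is exactly
    ``1 − (m_i + m_j)/L`` and all off-diagonal identities fall inside
    ``divergence_range`` by construction.  Per-taxon substitution loads are
    spread evenly across the admissible range, assigned in decreasing
    order (the first taxa returned are the most diverged from the rest).

    Copy numbers are drawn uniformly from 1–12 unless given explicitly.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    lo, hi = divergence_range
    if not (lo < hi) or not (0.5 < lo) or not (hi <= 1.0):
        raise ValueError(
            f"divergence_range must be an increasing pair within (0.5, 1.0], got {divergence_range}"
        )
    rng = np.random.default_rng(seed)
    ancestor = {g: _BASES[rng.integers(0, 4, size=L)] for g, L in GENE_LENGTHS.items()}

    # per-taxon mutated fraction: pairwise sums must land in [1-hi, 1-lo]
    if n_taxa == 1:
        fracs = np.array([(1.0 - hi) / 2.0])
    else:
        fracs = np.linspace((1.0 - lo) / 2.0, (1.0 - hi) / 2.0, n_taxa)

    per_gene_positions: dict[str, list[np.ndarray]] = {}
    for gene, L in GENE_LENGTHS.items():
        counts = np.maximum(1, np.rint(fracs * L).astype(int)) if n_taxa > 1 else \
            np.rint(fracs * L).astype(int)
        try:
            per_gene_positions[gene] = _disjoint_positions(rng, L, counts)
        except ValueError:
            if gene == "16S":
                raise  # 16S identities are contractual; refuse rather than drift
            # shorter genes: independent random positions, identity only approximate
            per_gene_positions[gene] = [
                np.sort(rng.choice(L, size=min(int(c), L), replace=False)) for c in counts
            ]

    if copy_numbers is None:
        copy_numbers = rng.integers(1, 13, size=n_taxa).tolist()
    elif len(copy_numbers) != n_taxa:
        raise ValueError("copy_numbers length must equal n_taxa")

    refs = []
    for i in range(n_taxa):
        genes = {
            g: _mutate(rng, ancestor[g], per_gene_positions[g][i]).tobytes().decode()
            for g in GENE_NAMES
        }
        refs.append(
            OperonReference(
                taxon_id=f"TAX{i + 1:02d}",
                lineage=("Bacteria", f"Phylum{i + 1:02d}", f"Class{i + 1:02d}",
                         f"Order{i + 1:02d}", f"Family{i + 1:02d}", f"Genus{i + 1:02d}"),
                genes=genes,
                copy_number=int(copy_numbers[i]),
            )
        )
    return refs


#: The demonstration condition: seven dominant taxa of a sulphidic,
#: anoxic subglacial lake plus one high-copy minor sulphate reducer.
#: (taxon_id, lineage domain→genus, cell fraction, operon copies)
DEMO_TAXA: tuple[tuple[str, tuple[str, ...], float, int], ...] = (
    ("Sulfuricurvum", ("Bacteria", "Proteobacteria", "Epsilonproteobacteria",
                       "Campylobacterales", "Helicobacteraceae", "Sulfuricurvum"), 0.300, 3),
    ("Acetobacterium", ("Bacteria", "Firmicutes", "Clostridia",
                        "Clostridiales", "Eubacteriaceae", "Acetobacterium"), 0.220, 5),
    ("Sulfurospirillum", ("Bacteria", "Proteobacteria", "Epsilonproteobacteria",
                          "Campylobacterales", "Campylobacteraceae", "Sulfurospirillum"), 0.140, 2),
    ("Geobacter_Pelobacter", ("Bacteria", "Proteobacteria", "Deltaproteobacteria",
                              "Desulfuromonadales", "Desulfuromonadaceae", "Geobacter"), 0.130, 4),
    ("Saccharibacteria", ("Bacteria", "Saccharibacteria", "Saccharibacteria_cl",
                          "Saccharibacteria_or", "Saccharibacteria_fa", "Saccharibacteria_ge"), 0.095, 1),
    ("Caldisericum", ("Bacteria", "Caldiserica", "Caldisericia",
                      "Caldisericales", "Caldisericaceae", "Caldisericum"), 0.060, 1),
    ("Prolixibacteraceae", ("Bacteria", "Bacteroidetes", "Bacteroidia",
                            "Bacteroidales", "Prolixibacteraceae", "Prolixibacteraceae_ge"), 0.047, 2),
    ("Desulfosporosinus", ("Bacteria", "Firmicutes", "Clostridia",
                           "Clostridiales", "Peptococcaceae", "Desulfosporosinus"), 0.008, 11),
)


def demo_community(
    seed: int,
    divergence_range: tuple[float, float] = (0.83, 0.99),
) -> tuple[MockCommunity, list[OperonReference]]:
    """Build the default 7-dominant + 1-minor community and its references."""
    raw = build_mock_operons(seed, len(DEMO_TAXA), divergence_range,
                             copy_numbers=[t[3] for t in DEMO_TAXA])
    refs = [op.with_identity(t[0], t[1], t[3]) for op, t in zip(raw, DEMO_TAXA)]
    community = MockCommunity(
        tuple(MockTaxon(t[0], t[1], t[2], t[3]) for t in DEMO_TAXA)
    )
    return community, check_unique_taxa(refs)


def random_taxonomy(rng: np.random.Generator) -> "TaxonomyTree":
    """Random ragged lineage tree with skewed (Pareto) leaf abundances.

    Labels come from a small pool so lineages share prefixes and the
    collapsing step has genuinely close relatives to choose between.
    """
    from .community import TaxonomyTree  # avoid a module cycle at import time

    n_leaves = int(rng.integers(2, 20))
    paths: set[tuple[str, ...]] = set()
    while len(paths) < n_leaves:
        depth = int(rng.integers(2, 7))
        path = tuple(f"{'dpcofg'[d]}{rng.integers(0, 3)}" for d in range(depth))
        # a node cannot be both internal and leaf: skip prefixes/extensions
        if any(p[:len(path)] == path or path[:len(p)] == p for p in paths):
            continue
        paths.add(path)
    abundances = rng.pareto(1.2, size=len(paths)) + 0.01
    return TaxonomyTree.from_records(
        (path, float(ab)) for path, ab in zip(sorted(paths), abundances)
    )


TRUTH_COLUMNS = ("read_id", "taxon_id", "gene", "start", "strand")


def simulate_reads(
    community: MockCommunity,
    refs: Sequence[OperonReference],
    config: SimulationConfig,
) -> tuple[list[tuple[ReadRecord, ReadRecord]], pd.DataFrame]:
    """Simulate overlapping innie read pairs from the community's operons.

    The expected pair count of taxon *t*, gene *g* is proportional to
    ``cell_fraction × copy_number × gene_length`` — the raw library is
    copy-number biased on purpose.  Returns the pairs plus a ground-truth
    table mapping each read id to (taxon, gene, fragment start, strand).
    """
    ref_by_id = {r.taxon_id: r for r in check_unique_taxa(refs)}
    missing = [t.taxon_id for t in community.taxa if t.taxon_id not in ref_by_id]
    if missing:
        raise ValueError(f"community taxa without a reference operon: {missing}")

    rng = np.random.default_rng(config.seed)
    rl = config.read_length

    cells: list[tuple[str, str, np.ndarray, float]] = []
    for t in community.taxa:
        for gene, seq in ref_by_id[t.taxon_id].genes.items():
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            if len(arr) < rl:
                continue  # gene too short to yield a full-length read
            cells.append((t.taxon_id, gene,
                          arr, t.cell_fraction * t.operon_copy_number * len(arr)))
    weights = np.array([c[3] for c in cells])
    unit = sum(t.cell_fraction * t.operon_copy_number *
               sum(ref_by_id[t.taxon_id].gene_lengths.values())
               for t in community.taxa)
    n_total = int(round(config.depth * unit / 1000.0))
    counts = rng.multinomial(n_total, weights / weights.sum())

    pairs: list[tuple[ReadRecord, ReadRecord]] = []
    truth_rows: list[tuple] = []
    serial = 0
    for (taxon, gene, arr, _), n in zip(cells, counts):
        L = len(arr)
        if n == 0:
            continue
        frags = np.rint(rng.normal(config.insert_mean, config.insert_sd, size=n))
        frags = np.clip(frags, rl, min(L, 2 * rl - 1)).astype(int)
        starts = (rng.random(n) * (L - frags + 1)).astype(int)
        strands = rng.random(n) < 0.5
        for j in range(n):
            f, s = frags[j], starts[j]
            frag = arr[s:s + f]
            strand = "-" if strands[j] else "+"
            if strand == "-":
                frag = _revcomp_bytes(frag)
            r1 = frag[:rl].copy()
            r2 = _revcomp_bytes(frag)[:rl].copy()
            rid = f"read_{serial:07d}"
            serial += 1
            recs = []
            for seq_arr in (r1, r2):
                qual = np.full(len(seq_arr), HIGH_QUALITY, dtype=np.int64)
                if config.per_base_error_rate > 0:
                    err = rng.random(len(seq_arr)) < config.per_base_error_rate
                    if err.any():
                        pos = np.flatnonzero(err)
                        seq_arr[pos] = _mutate(rng, seq_arr, pos)[pos]
                        lowq = rng.random(len(pos)) < 0.5
                        qual[pos[lowq]] = LOW_QUALITY
                recs.append(ReadRecord(rid, seq_arr.tobytes().decode(), qual))
            pairs.append((recs[0], recs[1]))
            truth_rows.append((rid, taxon, gene, int(s), strand))

    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))
    return pairs, truth


def write_fastq_pairs(
    pairs: Iterable[tuple[ReadRecord, ReadRecord]],
    r1_path: str | Path,
    r2_path: str | Path,
) -> None:
    """Write mates to ``*_R1.fastq`` / ``*_R2.fastq`` (Sanger Phred+33)."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for r1, r2 in pairs:
            for rec, fh, tag in ((r1, f1, "/1"), (r2, f2, "/2")):
                qual = "".join(chr(q + 33) for q in rec.qualities)
                fh.write(f"@{rec.id}{tag}\n{rec.sequence}\n+\n{qual}\n")


def make_annotation_table(
    community: MockCommunity,
    pathways: Sequence[PathwayDefinition],
    completeness_plan: Mapping[str, Mapping[str, float]],
    seed: int,
    n_decoys: int = 0,
) -> pd.DataFrame:
    """Build an ORF annotation table with a planned completeness per cell.

    For each (taxon, pathway, fraction) the plan requests, exactly
    ``round(fraction × n_genes)`` distinct required genes get one ORF row
    each, with percent identity in [0.60, 1.0] so the rows survive the
    default identity filter.  ``n_decoys`` adds sub-threshold rows
    (identity in [0.40, 0.60)) for genes *outside* the plan, giving the
    filter real work.

    Planned fractions are recovered exactly only when the planned pathways
    are gene-disjoint: a gene shared by two pathways (frdA/frdB sit in
    both the reductive citric acid cycle and fumarate respiration) counts
    toward both once emitted for either.
    """
    by_id = {p.pathway_id: p for p in pathways}
    vocab = sorted({g for p in pathways for g in p.required_genes})
    ko = {g: f"K{i + 1:05d}" for i, g in enumerate(vocab)}
    known = {t.taxon_id for t in community.taxa}
    rng = np.random.default_rng(seed)

    rows: list[dict] = []
    serial = 0
    for taxon_id in sorted(completeness_plan):
        if taxon_id not in known:
            raise ValueError(f"completeness_plan names unknown taxon {taxon_id!r}")
        for pathway_id in sorted(completeness_plan[taxon_id]):
            if pathway_id not in by_id:
                raise ValueError(f"unknown pathway id {pathway_id!r}")
            frac = completeness_plan[taxon_id][pathway_id]
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"completeness fraction outside [0, 1]: {frac}")
            genes = sorted(by_id[pathway_id].required_genes)
            k = int(round(frac * len(genes)))
            chosen = rng.choice(len(genes), size=k, replace=False)
            for gi in sorted(chosen):
                rows.append({
                    "orf_id": f"orf_{serial:06d}",
                    "gene_symbol": genes[gi],
                    "ko_id": ko[genes[gi]],
                    "percent_identity": round(float(rng.uniform(0.60, 1.00)), 4),
                    "taxon_id": taxon_id,
                    "read_support": int(rng.integers(1, 200)),
                })
                serial += 1
    taxa_sorted = sorted(known)
    for _ in range(n_decoys):
        g = vocab[int(rng.integers(0, len(vocab)))]
        rows.append({
            "orf_id": f"orf_{serial:06d}",
            "gene_symbol": g,
            "ko_id": ko[g],
            "percent_identity": round(float(rng.uniform(0.40, 0.5999)), 4),
            "taxon_id": taxa_sorted[int(rng.integers(0, len(taxa_sorted)))],
            "read_support": int(rng.integers(1, 200)),
        })
        serial += 1
    return pd.DataFrame(
        rows, columns=["orf_id", "gene_symbol", "ko_id",
                       "percent_identity", "taxon_id", "read_support"]
    )
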
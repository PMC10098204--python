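"""rDNA read recruitment against reference operons.

Reads are assigned to reference genes under a dual stringency threshold
(by default ≥98% identity over the aligned columns and ≥50% of the read
aligned), each read keeping at most its single best hit so that counts
partition the read pool.  Per-position coverage profiles feed a
homogeneity test that rejects references recruited only over a short
segment — the signature of a conserved-fragment artefact rather than a
genuinely present full-length gene.

Candidate placements are found by exact k-mer seeding and verified with a
semi-global (edlib) alignment in a padded window; identity is computed
over aligned columns including gaps.  A read overhanging a gene end is
clipped to the in-gene part, which reduces its read_coverage.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np

from .read_prep import ReadRecord
from .references import OperonReference, check_unique_taxa

_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class RecruitmentHit:
    """One read accepted against one reference gene (0-based, half-open)."""

    read_id: str
    taxon_id: str
    gene: str
    ref_start: int
    ref_end: int
    identity: float
    read_coverage: float
    strand: str
    aligned_length: int

    def __post_init__(self) -> None:
        if not self.ref_start < self.ref_end:
            raise ValueError("ref_start must be < ref_end")


@dataclass
class CoverageProfile:
    taxon_id: str
    gene: str
    depth: np.ndarray

    @property
    def breadth(self) -> float:
        """Fraction of reference positions covered by at least one read."""
        return float(np.count_nonzero(self.depth) / len(self.depth))


@dataclass(frozen=True)
class HomogeneityResult:
    accepted: bool
    breadth: float
    n_blocks: int
    largest_block_share: float
    largest_block_length: int

    @property
    def verdict(self) -> str:
        return "accepted" if self.accepted else "artefact"


def _revcomp(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr[::-1]]


class _SeedIndex:
    """Exact k-mer index over all reference genes (forward strand)."""

    def __init__(self, refs: Sequence[OperonReference], k: int):
        self.k = k
        self.genes: dict[tuple[str, str], bytes] = {}
        self.index: dict[bytes, list[tuple[str, str, int]]] = defaultdict(list)
        for ref in refs:
            for gene, seq in ref.genes.items():
                key = (ref.taxon_id, gene)
                enc = seq.encode()
                self.genes[key] = enc
                for pos in range(0, len(enc) - k + 1):
                    self.index[enc[pos:pos + k]].append((ref.taxon_id, gene, pos))

    def candidates(self, read: bytes, stride: int) -> set[tuple[str, str, int]]:
        """(taxon, gene, diagonal) placements suggested by shared k-mers."""
        out: set[tuple[str, str, int]] = set()
        k = self.k
        top = len(read) - k
        if top < 0:
            return out
        offsets = list(range(0, top + 1, stride))
        if offsets[-1] != top:
            offsets.append(top)  # always seed the read's tail
        for off in offsets:
            for taxon, gene, pos in self.index.get(read[off:off + k], ()):
                out.add((taxon, gene, pos - off))
        return out


def _align_segment(segment: bytes, window: bytes) -> tuple[float, int, int, int] | None:
    """Semi-global alignment of segment inside window.

    Returns (identity over aligned columns, columns, window_start,
    window_end) or None when edlib finds nothing.
    """
    res = edlib.align(segment, window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    matches = columns = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        columns += n
        if op == "=":
            matches += n
    start, end = res["locations"][0]
    return matches / columns, columns, start, end + 1


def recruit(
    reads: Iterable[ReadRecord],
    refs: Sequence[OperonReference],
    min_identity: float = 0.98,
    min_coverage: float = 0.50,
    seed_k: int = 15,
    seed_stride: int = 20,
    window_pad: int = 8,
) -> list[RecruitmentHit]:
    """Recruit reads against both strands of every reference gene.

    A read yields at most one hit — the best by (identity, aligned
    length, then lexicographically smallest taxon_id) — and only if both
    thresholds pass.  ``seed_k``/``seed_stride`` control candidate
    discovery: any read passing the identity threshold contains a long
    error-free stretch, so defaults are safe for reads of ~90 bp and up;
    lower them for very short reads.
    """
    refs = check_unique_taxa(refs)
    if not refs:
        raise ValueError("references must be non-empty")
    if not (0.0 < min_identity <= 1.0 and 0.0 < min_coverage <= 1.0):
        raise ValueError("thresholds must be in (0, 1]")
    idx = _SeedIndex(refs, seed_k)

    hits: list[RecruitmentHit] = []
    for read in reads:
        fwd = np.frombuffer(read.sequence.encode(), dtype=np.uint8)
        L = len(fwd)
        if L == 0:
            continue
        best: tuple | None = None  # sort key, hit fields
        for strand, arr in (("+", fwd), ("-", _revcomp(fwd))):
            enc = arr.tobytes()
            for taxon, gene, diag in idx.candidates(enc, seed_stride):
                gene_seq = idx.genes[(taxon, gene)]
                glen = len(gene_seq)
                a = max(0, -diag)                    # clip read to gene bounds
                b = L - max(0, diag + L - glen)
                if b - a < max(1, int(np.ceil(min_coverage * L))):
                    continue
                w_lo = max(0, diag + a - window_pad)
                w_hi = min(glen, diag + b + window_pad)
                aln = _align_segment(enc[a:b], gene_seq[w_lo:w_hi])
                if aln is None:
                    continue
                identity, columns, s, e = aln
                coverage = (b - a) / L
                if identity < min_identity or coverage < min_coverage:
                    continue
                key = (identity, columns, _NEG_LEX(taxon), gene, strand)
                if best is None or key > best[0]:
                    best = (key, (taxon, gene, w_lo + s, w_lo + e,
                                  identity, coverage, strand, columns))
        if best is not None:
            taxon, gene, rs, re_, ident, cov, strand, columns = best[1]
            hits.append(RecruitmentHit(read.id, taxon, gene, rs, re_,
                                       ident, cov, strand, columns))
    return hits


class _NEG_LEX(str):
    """Wrapper making lexicographically *smaller* strings sort *greater*."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def coverage_profiles(
    hits: Iterable[RecruitmentHit],
    refs: Sequence[OperonReference],
) -> list[CoverageProfile]:
    """Per-position depth for every (taxon, gene), including uncovered ones."""
    lengths = {(r.taxon_id, g): len(s) for r in refs for g, s in r.genes.items()}
    depth = {key: np.zeros(n, dtype=np.int64) for key, n in lengths.items()}
    for hit in hits:
        key = (hit.taxon_id, hit.gene)
        if key not in depth:
            raise ValueError(f"hit on unknown reference gene {key}")
        if hit.ref_end > lengths[key]:
            raise ValueError(f"hit beyond gene end: {hit}")
        depth[key][hit.ref_start:hit.ref_end] += 1
    return [CoverageProfile(t, g, d) for (t, g), d in depth.items()]


def homogeneity_test(
    profile: CoverageProfile,
    min_breadth: float = 0.5,
    window: int = 100,
    block_share: float = 0.95,
    max_block_fraction: float = 0.20,
) -> HomogeneityResult:
    """Coverage-homogeneity artefact test.

    A reference is called an artefact when its breadth falls below
    ``min_breadth`` (strictly — breadth exactly at the threshold is
    accepted), or when at least ``block_share`` of all aligned bases sit
    in one contiguous covered block spanning less than
    ``max_block_fraction`` of the gene: reads piling onto a single short
    conserved segment do not evidence the full-length gene.
    """
    depth = profile.depth
    n = len(depth)
    if n < window:
        raise ValueError(f"profile length {n} shorter than window {window}")
    covered = depth > 0
    breadth = profile.breadth

    # contiguous covered blocks and their aligned-base mass
    edges = np.flatnonzero(np.diff(np.concatenate([[0], covered.view(np.int8), [0]])))
    starts, ends = edges[::2], edges[1::2]
    block_mass = np.array([depth[s:e].sum() for s, e in zip(starts, ends)], dtype=float)
    n_blocks = len(starts)
    if n_blocks:
        big = int(np.argmax(block_mass))
        share = float(block_mass[big] / block_mass.sum())
        big_len = int(ends[big] - starts[big])
    else:
        share, big_len = 0.0, 0

    clustered = n_blocks > 0 and share >= block_share and big_len < max_block_fraction * n
    accepted = breadth >= min_breadth and not clustered
    return HomogeneityResult(accepted, breadth, n_blocks, share, big_len)


def filter_artefacts(
    hits: Sequence[RecruitmentHit],
    refs: Sequence[OperonReference],
    min_breadth: float = 0.5,
    window: int = 100,
    block_share: float = 0.95,
    max_block_fraction: float = 0.20,
) -> tuple[list[RecruitmentHit], dict[tuple[str, str], HomogeneityResult]]:
    """Drop hits on (taxon, gene) references failing the homogeneity test.

    References with no hits at all are reported (breadth 0) but have
    nothing to drop.  Genes shorter than ``window`` are exempted from the
    test rather than erroring, so a 5S gene never trips the guard.
    """
    results: dict[tuple[str, str], HomogeneityResult] = {}
    for prof in coverage_profiles(hits, refs):
        if len(prof.depth) < window:
            continue
        if prof.depth.any():
            results[(prof.taxon_id, prof.gene)] = homogeneity_test(
                prof, min_breadth, window, block_share, max_block_fraction
            )
    rejected = {key for key, res in results.items() if not res.accepted}
    kept = [h for h in hits if (h.taxon_id, h.gene) not in rejected]
    return kept, results


def hits_to_counts(hits: Iterable[RecruitmentHit]) -> dict[str, dict[str, int]]:
    """Raw read counts per taxon per gene."""
    counts: dict[str, dict[str, int]] = {}
    for hit in hits:
        counts.setdefault(hit.taxon_id, {}).setdefault(hit.gene, 0)
        counts[hit.taxon_id][hit.gene] += 1
    return counts
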
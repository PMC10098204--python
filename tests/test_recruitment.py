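"""Recruitment thresholds, best-hit assignment, coverage and artefact logic."""

import numpy as np
import pytest

import mitagprofiler as m
from mitagprofiler.recruitment import CoverageProfile, homogeneity_test

from .conftest import random_dna, revcomp


def make_read(rid, seq):
    return m.ReadRecord(rid, seq, np.full(len(seq), 37))


@pytest.fixture(scope="module")
def three_refs():
    return m.build_mock_operons(21, 3, (0.85, 0.94))


class TestRecruit:
    def test_exact_substring_hits_with_full_identity(self, three_refs):
        gene = three_refs[0].genes["16S"]
        read = make_read("r0", gene[400:508])
        (hit,) = m.recruit([read], three_refs)
        assert hit.taxon_id == three_refs[0].taxon_id
        assert hit.gene == "16S"
        assert hit.identity == 1.0
        assert hit.read_coverage == 1.0
        assert (hit.ref_start, hit.ref_end) == (400, 508)
        assert hit.strand == "+"

    def test_reverse_strand_reads_recruited(self, three_refs):
        gene = three_refs[1].genes["23S"]
        read = make_read("r1", revcomp(gene[1000:1157]))
        (hit,) = m.recruit([read], three_refs)
        assert (hit.taxon_id, hit.gene, hit.strand) == (
            three_refs[1].taxon_id, "23S", "-")
        assert (hit.ref_start, hit.ref_end) == (1000, 1157)

    @pytest.mark.parametrize(("aligned", "expect_hit"), [(54, True), (53, False)])
    def test_read_coverage_threshold_on_gene_overhang(self, three_refs,
                                                      aligned, expect_hit):
        """A 108-base read with only `aligned` bases inside the gene end:
        50% read coverage is the inclusive boundary."""
        gene = three_refs[0].genes["16S"]
        rng = np.random.default_rng(99)
        read = make_read("rb", gene[-aligned:] + random_dna(rng, 108 - aligned))
        hits = m.recruit([read], three_refs)
        if expect_hit:
            (hit,) = hits
            assert hit.read_coverage == pytest.approx(54 / 108)
            assert hit.identity == 1.0
            assert hit.ref_end == len(gene)
        else:
            assert hits == []

    def test_diverged_decoy_reads_rarely_recruited(self, three_refs):
        """1,000 reads from a 10%-diverged taxon: recruitment rate < 1%."""
        rng = np.random.default_rng(77)
        src = np.frombuffer(three_refs[0].genes["16S"].encode(), np.uint8)
        n_mut = int(round(0.10 * len(src)))
        pos = rng.choice(len(src), size=n_mut, replace=False)
        decoy = src.copy()
        bases = np.frombuffer(b"ACGT", np.uint8)
        idx = np.searchsorted(bases, decoy[pos])
        decoy[pos] = bases[(idx + rng.integers(1, 4, size=n_mut)) % 4]
        decoy_seq = decoy.tobytes().decode()
        starts = rng.integers(0, len(decoy_seq) - 157, size=1000)
        reads = [make_read(f"d{i}", decoy_seq[s:s + 157])
                 for i, s in enumerate(starts)]
        hits = m.recruit(reads, three_refs)
        assert len(hits) / 1000 < 0.01

    def test_sensitivity_and_misassignment_on_ground_truth(self):
        """Error-free reads, references <=95%% inter-taxon identity:
        >=99%% recruited, <=0.1%% to the wrong taxon."""
        refs = m.build_mock_operons(31, 5, (0.85, 0.94))
        community = m.MockCommunity(tuple(
            m.MockTaxon(r.taxon_id, r.lineage, 0.2, r.copy_number) for r in refs
        ))
        cfg = m.SimulationConfig(per_base_error_rate=0.0, depth=120, seed=31)
        pairs, truth = m.simulate_reads(community, refs, cfg)
        cleaned, _ = m.prep_reads(pairs)
        hits = m.recruit(cleaned, refs)
        assert len(hits) / len(cleaned) >= 0.99
        tmap = dict(zip(truth.read_id, truth.taxon_id))
        wrong = sum(1 for h in hits if tmap[h.read_id] != h.taxon_id)
        assert wrong / len(hits) <= 0.001

    def test_lowering_identity_never_loses_hits(self, three_refs):
        """Monotonicity in the identity threshold, on noisy reads."""
        rng = np.random.default_rng(13)
        gene = three_refs[2].genes["16S"]
        reads = []
        for i in range(120):
            s = int(rng.integers(0, len(gene) - 140))
            arr = list(gene[s:s + 140])
            for p in rng.choice(140, size=int(rng.integers(0, 6)), replace=False):
                arr[p] = "ACGT"[int(rng.integers(0, 4))]
            reads.append(make_read(f"m{i}", "".join(arr)))
        counts = [len(m.recruit(reads, three_refs, min_identity=t))
                  for t in (1.0, 0.99, 0.98, 0.97, 0.95)]
        assert counts == sorted(counts)

    def test_duplicate_taxon_ids_rejected(self, three_refs):
        with pytest.raises(ValueError, match="duplicate"):
            m.recruit([], [three_refs[0], three_refs[0]])

    def test_matches_brute_force_hamming_oracle(self):
        """On tiny references and short reads the seeded aligner must agree
        exactly with an all-offsets Hamming scan."""
        rng = np.random.default_rng(55)
        refs = [
            m.OperonReference(f"T{i}", ("Bacteria", f"G{i}"),
                              {"16S": random_dna(rng, 200)}, 1)
            for i in range(3)
        ]
        reads = []
        for i in range(60):
            ref = refs[int(rng.integers(0, 3))]
            s = int(rng.integers(0, 200 - 30))
            seq = list(ref.genes["16S"][s:s + 30])
            if rng.random() < 0.4:  # occasional single mutation
                p = int(rng.integers(0, 30))
                seq[p] = "ACGT"[int(rng.integers(0, 4))]
            seq = "".join(seq)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append(make_read(f"o{i}", seq))

        got = {h.read_id: h for h in m.recruit(
            reads, refs, min_identity=0.98, min_coverage=0.5,
            seed_k=8, seed_stride=1)}
        expected = {h.read_id: h for h in
                    (self._oracle(r, refs, 0.98, 0.5) for r in reads)
                    if h is not None}
        assert set(got) == set(expected)
        for rid, hit in expected.items():
            g = got[rid]
            assert (g.taxon_id, g.gene, g.strand) == (
                hit.taxon_id, hit.gene, hit.strand)
            assert (g.ref_start, g.ref_end) == (hit.ref_start, hit.ref_end)
            assert g.identity == pytest.approx(hit.identity)
            assert g.read_coverage == pytest.approx(hit.read_coverage)

    @staticmethod
    def _oracle(read, refs, min_identity, min_coverage):
        """All-offsets Hamming scan with the same best-hit tie rule."""
        best_key, best = None, None
        L = len(read.sequence)
        for strand, seq in (("+", read.sequence), ("-", revcomp(read.sequence))):
            for ref in refs:
                for gene, gseq in ref.genes.items():
                    G = len(gseq)
                    for diag in range(-L + 1, G):
                        a = max(0, -diag)
                        b = L - max(0, diag + L - G)
                        if b - a < 1:
                            continue
                        seg, win = seq[a:b], gseq[diag + a:diag + b]
                        matches = sum(x == y for x, y in zip(seg, win))
                        ident = matches / (b - a)
                        cov = (b - a) / L
                        if ident < min_identity or cov < min_coverage:
                            continue
                        key = (ident, b - a,
                               tuple(-ord(c) for c in ref.taxon_id),
                               gene, strand)
                        if best_key is None or key > best_key:
                            best_key = key
                            best = m.RecruitmentHit(
                                read.id, ref.taxon_id, gene, diag + a, diag + b,
                                ident, cov, strand, b - a)
        return best


class TestCoverage:
    def test_no_hits_gives_zero_breadth(self, three_refs):
        profiles = m.coverage_profiles([], three_refs)
        assert len(profiles) == 9
        assert all(p.breadth == 0.0 for p in profiles)

    def test_single_hit_breadth_arithmetic(self, three_refs):
        hit = m.RecruitmentHit("r", three_refs[0].taxon_id, "16S", 0, 108,
                               1.0, 1.0, "+", 108)
        profiles = {(p.taxon_id, p.gene): p
                    for p in m.coverage_profiles([hit], three_refs)}
        p = profiles[(three_refs[0].taxon_id, "16S")]
        assert p.breadth == pytest.approx(108 / 1819)
        assert p.depth.sum() == 108

    def test_out_of_bounds_hit_is_integrity_error(self, three_refs):
        bad = m.RecruitmentHit("r", three_refs[0].taxon_id, "5S", 100, 300,
                               1.0, 1.0, "+", 200)
        with pytest.raises(ValueError, match="beyond"):
            m.coverage_profiles([bad], three_refs)


class TestHomogeneity:
    def test_conserved_fragment_pileup_is_artefact(self):
        """Reads confined to positions 850-1000 of a full-length 16S."""
        depth = np.zeros(1819, dtype=np.int64)
        depth[850:1000] = 40
        result = homogeneity_test(CoverageProfile("arch", "16S", depth))
        assert not result.accepted
        assert result.breadth == pytest.approx(150 / 1819)

    def test_uniform_tiling_accepted(self):
        depth = np.full(1819, 3, dtype=np.int64)
        result = homogeneity_test(CoverageProfile("t", "16S", depth))
        assert result.accepted
        assert result.breadth == 1.0
        assert result.n_blocks == 1

    def test_breadth_exactly_at_threshold_is_accepted(self):
        """Rejection is strict-less: dispersed coverage at breadth == 0.5."""
        depth = np.zeros(200, dtype=np.int64)
        depth[0:50] = 1
        depth[100:150] = 1
        result = homogeneity_test(CoverageProfile("b", "16S", depth),
                                  min_breadth=0.5, window=100)
        assert result.breadth == 0.5
        assert result.accepted

    def test_clustered_mass_in_short_block_is_artefact_despite_breadth(self):
        depth = np.zeros(1000, dtype=np.int64)
        depth[0:100] = 100           # 10,000 aligned bases in a 10% block
        depth[200:600:1] = 1         # 400 dispersed singletons
        result = homogeneity_test(CoverageProfile("c", "16S", depth))
        assert result.breadth >= 0.5
        assert result.largest_block_share >= 0.95
        assert not result.accepted

    def test_short_gene_exempted_by_filter_wrapper(self, three_refs):
        hit = m.RecruitmentHit("r", three_refs[0].taxon_id, "5S", 0, 108,
                               1.0, 1.0, "+", 108)
        kept, results = m.filter_artefacts([hit], three_refs, window=120)
        assert kept == [hit]  # 5S (115 bp) < window: exempt, never rejected
        assert (three_refs[0].taxon_id, "5S") not in results
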
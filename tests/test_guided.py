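"""Gene-overlap scoring, dominance, and annotation-guided detection."""

from __future__ import annotations

import numpy as np
import pytest

import mitomarkers as mm
from mitomarkers.guided import project_annotations
from _oracles import dominance_ratio, is_antichain, window_gene_scores
from conftest import forward_only, random_sequences


class TestOverlap:
    def test_partial_overlap(self):
        occ = mm.Occurrence(0, 10, 20)
        ann = mm.GeneAnnotation("g0", "nad1", "+", 15, 40)
        assert mm.overlap(occ, ann) == 5

    def test_disjoint_is_zero(self):
        occ = mm.Occurrence(0, 10, 20)
        ann = mm.GeneAnnotation("g0", "nad1", "+", 30, 40)
        assert mm.overlap(occ, ann) == 0

    def test_nested_occurrence_counts_its_length(self):
        occ = mm.Occurrence(0, 12, 20)
        ann = mm.GeneAnnotation("g0", "nad1", "+", 0, 100)
        assert mm.overlap(occ, ann) == 8


class TestDominantGene:
    g, h = mm.GeneKey("nad1", "+"), mm.GeneKey("cox1", "+")

    def test_clear_majority(self):
        assert mm.dominant_gene({self.g: 96, self.h: 4}) == self.g

    def test_exact_threshold_fails_strict_inequality(self):
        assert mm.dominant_gene({self.g: 95, self.h: 5}) is None

    def test_empty_table_is_none(self):
        assert mm.dominant_gene({}) is None

    def test_tie_at_max_can_never_dominate(self):
        assert mm.dominant_gene({self.g: 50, self.h: 50}) is None


class TestScoring:
    def _setup(self, seqs, annotations, k=8):
        tree = mm.build_truncated_gst(forward_only(seqs), k)
        mm.score_leaves(tree, annotations)
        mm.propagate_scores(tree)
        return tree

    def test_leaf_tables_match_bruteforce_window_overlaps(self):
        rng = np.random.default_rng(31)
        seqs = random_sequences(rng, 4, 120, min_len=60)
        annotations = []
        for i, s in enumerate(seqs):
            a = int(rng.integers(0, len(s) // 2))
            b = a + int(rng.integers(10, 40))
            annotations.append(mm.GeneAnnotation(f"s{i}", "nad1", "+", a, b))
            c = min(b + int(rng.integers(0, 20)), len(s) - 5)
            annotations.append(
                mm.GeneAnnotation(f"s{i}", "cox1", "-", c, min(c + 30, len(s)))
            )
        k = 8
        tree = self._setup(seqs, annotations, k)
        proj = project_annotations(tree, annotations)
        for node in tree.iter_nodes():
            word = tree.node_word(node.node_id)
            if not word or tree.has_sentinel(node.node_id):
                continue
            expected = window_gene_scores(word, seqs, proj, k)
            assert mm.scores_table(tree, node.node_id) == expected, word

    def test_parent_table_is_sum_of_children(self):
        rng = np.random.default_rng(33)
        seqs = random_sequences(rng, 5, 100, min_len=50)
        annotations = [
            mm.GeneAnnotation(f"s{i}", "nad1", "+", 5, 40) for i in range(len(seqs))
        ]
        tree = self._setup(seqs, annotations)
        for node in tree.iter_nodes():
            if not node.children:
                continue
            summed = {}
            for child in node.children.values():
                for key, v in mm.scores_table(tree, child).items():
                    summed[key] = summed.get(key, 0) + v
            assert mm.scores_table(tree, node.node_id) == summed

    def test_root_table_sums_all_leaves(self):
        rng = np.random.default_rng(35)
        seqs = random_sequences(rng, 3, 80, min_len=40)
        annotations = [mm.GeneAnnotation("s0", "nad1", "+", 0, 30)]
        tree = self._setup(seqs, annotations)
        leaf_total = {}
        for node in tree.iter_nodes():
            if node.is_leaf:
                for key, v in mm.scores_table(tree, node.node_id).items():
                    leaf_total[key] = leaf_total.get(key, 0) + v
        assert mm.scores_table(tree, tree.root) == leaf_total

    def test_unknown_source_id_rejected(self):
        tree = mm.build_truncated_gst(forward_only(["ACGTACGT"]), 4)
        with pytest.raises(ValueError, match="unknown source"):
            mm.score_leaves(tree, [mm.GeneAnnotation("nope", "nad1", "+", 0, 4)])

    def test_rc_projection_flips_strand_and_mirrors(self):
        genomes = [("g0", "AAACCCGGGTTTAAAC")]
        ann = [mm.GeneAnnotation("g0", "nad1", "+", 3, 9)]  # CCCGGG
        derived = mm.expand_with_reverse_complements(genomes)
        tree = mm.build_truncated_gst(derived, 6)
        proj = project_annotations(tree, ann)
        assert proj[0] == [(3, 9, mm.GeneKey("nad1", "+"))]
        # on the RC copy (length 16): [16-9, 16-3) with strand flipped
        assert proj[1] == [(7, 13, mm.GeneKey("nad1", "-"))]


@pytest.fixture(scope="module")
def conserved_block():
    """Ten genomes sharing one identical 40-nt gene block in random
    background, annotated exactly."""
    rng = np.random.default_rng(55)
    block = "".join("ACGT"[c] for c in rng.integers(0, 4, 40))
    genomes, annotations = [], []
    for i in range(10):
        bg = "".join("ACGT"[c] for c in rng.integers(0, 4, 400))
        pos = int(rng.integers(50, 350))
        genomes.append((f"g{i}", bg[:pos] + block + bg[pos:]))
        annotations.append(mm.GeneAnnotation(f"g{i}", "nad1", "+", pos, pos + 40))
    ds = mm.make_dataset(genomes, annotations)
    tree = mm.build_truncated_gst(ds.derived, 30)
    return block, genomes, annotations, tree


class TestDetectGuided:

    def test_markers_found_with_correct_target(self, conserved_block):
        block, genomes, annotations, tree = conserved_block
        markers = mm.detect_guided(tree, annotations)
        plus = [m for m in markers if m.target == mm.GeneKey("nad1", "+")]
        assert plus
        inside = [m for m in plus if m.word in block]
        assert inside

        def fully_inside(m):
            for occ in tree.find_all([m.word])[m.word]:
                seq = tree.sequences[occ.seq_index]
                if seq.strand != "+":
                    continue
                ann = next(a for a in annotations if a.source_id == seq.source_id)
                if occ.start < ann.start or occ.end > ann.end:
                    return False
            return True

        # at least one marker is specific: every forward occurrence lies
        # inside the annotated gene copies (short markers may additionally
        # hit unannotated background, which dominance does not penalize)
        assert any(fully_inside(m) for m in inside)

    def test_rc_copies_yield_minus_strand_markers(self, conserved_block):
        _, _, annotations, tree = conserved_block
        markers = mm.detect_guided(tree, annotations)
        assert any(m.target == mm.GeneKey("nad1", "-") for m in markers)

    def test_markers_validated_by_bruteforce_dominance(self, conserved_block):
        """Every emitted marker dominates under an independent window-overlap
        recount, and its one-symbol-shorter parent word does not."""
        _, _, annotations, tree = conserved_block
        seqs = [s.residues for s in tree.sequences]
        proj = project_annotations(tree, annotations)
        markers = mm.detect_guided(tree, annotations)
        for m in markers:
            scores = window_gene_scores(m.word, seqs, proj, tree.k)
            assert dominance_ratio(scores) > 0.95
            best = max(scores, key=lambda k: (scores[k], k))
            assert best == m.target
            parent_word = m.word[:-1]
            if parent_word:
                parent_scores = window_gene_scores(parent_word, seqs, proj, tree.k)
                assert dominance_ratio(parent_scores) <= 0.95

    def test_emitted_set_is_antichain_with_support(self, conserved_block):
        _, _, annotations, tree = conserved_block
        markers = mm.detect_guided(tree, annotations)
        assert is_antichain([m.word for m in markers])
        for m in markers:
            assert m.support >= 2
            assert not mm.contains_repeat(m.word)
            assert m.support == tree.count_of(m.word)

    def test_empty_annotations_rejected(self, conserved_block):
        *_, tree = conserved_block
        with pytest.raises(ValueError, match="requires annotations"):
            mm.detect_guided(tree, [])

    def test_only_annotated_gene_can_become_target(self):
        rng = np.random.default_rng(60)
        seqs = random_sequences(rng, 4, 200, min_len=150)
        genomes = [(f"s{i}", s) for i, s in enumerate(seqs)]
        # annotate a region of the first genome only; a node with zero total
        # score is never dominant, so every marker must target that gene
        ann = [mm.GeneAnnotation("s0", "nad1", "+", 0, 10)]
        tree = mm.build_truncated_gst(mm.expand_with_reverse_complements(genomes), 10)
        markers = mm.detect_guided(tree, ann)
        for m in markers:
            assert m.target.gene == "nad1"

    def test_robust_to_injected_annotation_errors(self):
        """With 5% strand flips / renames, at least 90% of markers keep the
        true generating gene as target."""
        params = mm.mini_params(
            n_genomes=15, mutation_rate=0.03, seed=909,
            error_rates=mm.AnnotationErrorRates(strand_flip=0.025, gene_rename=0.025),
        )
        ds = mm.generate(params)
        tree = mm.build_truncated_gst(ds.dataset("observed").derived, 30)
        markers = mm.detect_guided(tree, ds.observed)
        clean = mm.classify_markers(sorted(markers, key=lambda m: m.word),
                                    tree, ds.truth)
        truth_target = {m.word: m.target for m in clean}
        agree = sum(1 for m in markers if m.target == truth_target[m.word])
        assert agree / len(markers) >= 0.90
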
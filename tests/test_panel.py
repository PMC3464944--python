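"""Panel I/O, alignment, divergence scanning, coordinate maps, generator."""

import itertools
from functools import lru_cache

import numpy as np
import pytest

from plantid.panel import (
    GAP,
    PanelError,
    Role,
    SequencePanel,
    SequenceRecord,
    align_panel,
    divergence_scan,
    gapped_to_ungapped,
    generate_synthetic_panel,
    pairwise_nw_score,
    read_panel,
    ungapped_to_gapped,
    write_panel,
)


def make_panel(seqs, roles=None):
    roles = roles or ["target"] * len(seqs)
    return SequencePanel([
        SequenceRecord(f"r{i}", f"sp{i}", Role(role), s)
        for i, (s, role) in enumerate(zip(seqs, roles))
    ])


class TestRecordsAndPanels:
    def test_sequences_are_uppercased_and_u_normalised(self):
        rec = SequenceRecord("a", "sp", Role.TARGET, "acgu")
        assert rec.sequence == "ACGT"

    @pytest.mark.parametrize("bad", ["", "ACGX", "AC-GT"])
    def test_invalid_sequences_rejected(self, bad):
        with pytest.raises(PanelError):
            SequenceRecord("a", "sp", Role.TARGET, bad)

    def test_duplicate_species_rejected(self):
        recs = [
            SequenceRecord("a", "sp", Role.TARGET, "ACGT"),
            SequenceRecord("b", "sp", Role.TARGET, "ACGT"),
        ]
        with pytest.raises(PanelError, match="duplicate species"):
            SequencePanel(recs)

    def test_alignment_must_ungap_to_raw_sequence(self):
        recs = [SequenceRecord("a", "sp", Role.TARGET, "ACGT")]
        with pytest.raises(PanelError, match="ungapping"):
            SequencePanel(recs, aligned=["AC-GA"])


class TestReadWrite:
    def test_roles_parsed_from_headers(self, tmp_path):
        fasta = tmp_path / "p.fasta"
        fasta.write_text(
            ">a1|Hypericum perforatum|target\nACGTACGT\n"
            ">a2|Hypericum calycinum|non_target\nACGTTCGT\n"
        )
        p = read_panel(fasta)
        assert p.targets == ["Hypericum perforatum"]
        assert p.non_targets == ["Hypericum calycinum"]

    def test_duplicate_species_in_fasta_is_an_error(self, tmp_path):
        fasta = tmp_path / "p.fasta"
        fasta.write_text(">a|sp|target\nACGT\n>b|sp|target\nACCT\n")
        with pytest.raises(PanelError):
            read_panel(fasta)

    def test_empty_fasta_is_an_error(self, tmp_path):
        fasta = tmp_path / "p.fasta"
        fasta.write_text("")
        with pytest.raises(PanelError):
            read_panel(fasta)

    def test_synthetic_panel_round_trips(self, tmp_path):
        p = generate_synthetic_panel(seed=1)
        path = tmp_path / "syn.fasta"
        write_panel(p, path)
        q = read_panel(path)
        assert [r.sequence for r in q.records] == [r.sequence for r in p.records]
        assert [r.species for r in q.records] == [r.species for r in p.records]
        assert [r.role for r in q.records] == [r.role for r in p.records]

    def test_aligned_round_trip_preserves_gaps(self, tmp_path):
        p = align_panel(make_panel(["ACGTACGT", "ACGACGT"]))
        path = tmp_path / "aln.fasta"
        write_panel(p, path, aligned=True)
        q = read_panel(path)
        assert q.aligned == p.aligned


def brute_force_nw(a, b, match=1.0, mismatch=-1.0, gap=-2.0):
    """Exhaustive optimal global alignment score by recursion over all paths."""

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap + rec(i, j + 1))
        return best

    return rec(0, 0)


class TestAlignment:
    def test_identical_sequences_align_gap_free(self):
        p = align_panel(make_panel(["ACGTACGT", "ACGTACGT"]))
        assert p.aligned == ["ACGTACGT", "ACGTACGT"]

    def test_single_deletion_opens_one_gap_column(self):
        p = align_panel(make_panel(["ACGT", "ACT"]))
        assert p.alignment_length == 4
        assert sum(row.count(GAP) for row in p.aligned) == 1
        assert pairwise_nw_score("ACGT", "ACT") == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_pairwise_score_matches_exhaustive_recursion(self, seed):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        for _ in range(10):
            a = "".join(rng.choice(bases, size=rng.integers(1, 7)))
            b = "".join(rng.choice(bases, size=rng.integers(1, 7)))
            assert pairwise_nw_score(a, b) == pytest.approx(brute_force_nw(a, b))

    def test_low_divergence_panel_aligns_at_high_identity(self):
        p = align_panel(generate_synthetic_panel(
            n_species=4, n_targets=2, spacer_divergence=0.02, seed=5))
        for r1, r2 in itertools.combinations(range(4), 2):
            a, b = p.aligned[r1], p.aligned[r2]
            ident = sum(x == y for x, y in zip(a, b) if x != GAP and y != GAP)
            compared = sum(1 for x, y in zip(a, b) if x != GAP and y != GAP)
            assert ident / compared >= 0.95

    def test_ungapping_invariant_holds_for_every_row(self, synthetic_panel):
        for row, rec in zip(synthetic_panel.aligned, synthetic_panel.records):
            assert row.replace(GAP, "") == rec.sequence

    def test_single_record_is_identity_alignment(self):
        p = align_panel(make_panel(["ACGT"]))
        assert p.aligned == ["ACGT"]


class TestDivergenceScan:
    def test_identical_rows_score_zero_everywhere(self):
        p = align_panel(make_panel(["ACGTACGTACGT"] * 3))
        assert all(pr.score == 0 for pr in divergence_scan(p, window=4, stride=2))

    def test_private_substitution_is_discriminating(self):
        p = SequencePanel(
            [
                SequenceRecord("a", "A", Role.TARGET, "ACGTACGT"),
                SequenceRecord("b", "B", Role.TARGET, "ACGTACGT"),
                SequenceRecord("c", "C", Role.TARGET, "ACGAACGT"),
            ],
            aligned=["ACGTACGT", "ACGTACGT", "ACGAACGT"],
        )
        profs = divergence_scan(p, window=4, stride=1)
        covering = [pr for pr in profs if pr.window_start <= 3 < pr.window_start + 4]
        assert all("C" in pr.discriminating_species for pr in covering)
        # A and B are mutually identical: never discriminating
        assert all(not {"A", "B"} & pr.discriminating_species for pr in profs)

    def test_window_longer_than_alignment_is_an_error(self):
        p = align_panel(make_panel(["ACGT", "ACGT"]))
        with pytest.raises(PanelError):
            divergence_scan(p, window=10)

    def test_scores_match_brute_force_window_comparison(self, synthetic_panel):
        window, stride = 20, 7
        profs = divergence_scan(synthetic_panel, window, stride)
        rows = synthetic_panel.aligned
        species = synthetic_panel.species
        expected = []
        for start in range(0, synthetic_panel.alignment_length - window + 1, stride):
            segs = [r[start:start + window] for r in rows]
            disc = {
                species[i]
                for i in range(len(rows))
                if segs.count(segs[i]) == 1
            }
            expected.append((start, disc))
        assert [(pr.window_start, set(pr.discriminating_species))
                for pr in profs] == expected


class TestCoordinateMaps:
    def test_gap_free_row_maps_identically(self):
        p = align_panel(make_panel(["ACGT"]))
        for i in range(4):
            assert gapped_to_ungapped(p, "sp0", i) == (i, False)
            assert ungapped_to_gapped(p, "sp0", i) == i

    def test_gap_column_maps_to_next_base_with_flag(self):
        p = SequencePanel(
            [SequenceRecord("a", "sp", Role.TARGET, "ACG")],
            aligned=["A-CG"],
        )
        assert gapped_to_ungapped(p, "sp", 1) == (1, True)
        assert gapped_to_ungapped(p, "sp", 2) == (1, False)

    def test_round_trip_is_identity_on_non_gap_columns(self, synthetic_panel):
        for sp in synthetic_panel.species[:3]:
            row = synthetic_panel.aligned_row(sp)
            for col, char in enumerate(row):
                if char == GAP:
                    continue
                pos, on_gap = gapped_to_ungapped(synthetic_panel, sp, col)
                assert not on_gap
                assert ungapped_to_gapped(synthetic_panel, sp, pos) == col


class TestSyntheticGenerator:
    def test_deterministic_for_fixed_seed(self):
        a = generate_synthetic_panel(seed=9)
        b = generate_synthetic_panel(seed=9)
        assert [r.sequence for r in a.records] == [r.sequence for r in b.records]

    def test_zero_divergence_warns_and_yields_identical_sequences(self):
        with pytest.warns(UserWarning, match="indistinguishable|identical"):
            p = generate_synthetic_panel(spacer_divergence=0.0, seed=2)
        assert len({r.sequence for r in p.records}) == 1

    def test_locus_structure_and_length(self):
        p = generate_synthetic_panel(seed=3)
        from plantid.panel import (
            CONSERVED_3P_FLANK,
            CONSERVED_5P_FLANK,
            CONSERVED_MID,
        )
        for r in p.records:
            assert 600 <= len(r.sequence) <= 800
            assert r.sequence.startswith(CONSERVED_5P_FLANK)
            assert r.sequence.endswith(CONSERVED_3P_FLANK)
            assert CONSERVED_MID in r.sequence

    def test_spacer_identity_matches_divergence_rate(self):
        # two independent 5% substitution draws -> pairwise identity ~ 0.905
        p = generate_synthetic_panel(
            n_species=7, n_targets=4, spacer_divergence=0.05, seed=11)
        from plantid.panel import CONSERVED_5P_FLANK, CONSERVED_MID
        idents = []
        for r1, r2 in itertools.combinations(p.records, 2):
            s1, s2 = r1.sequence, r2.sequence
            # spacer 1 occupies the region between the conserved blocks
            a, b = len(CONSERVED_5P_FLANK), s1.index(CONSERVED_MID)
            matches = sum(x == y for x, y in zip(s1[a:b], s2[a:b]))
            idents.append(matches / (b - a))
        assert np.mean(idents) == pytest.approx(0.90, abs=0.03)

    def test_target_count_must_not_exceed_species_count(self):
        with pytest.raises(PanelError):
            generate_synthetic_panel(n_species=3, n_targets=4)
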
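"""Deletion enumeration, oligo geometry, clean chimeras, gRNA uniqueness."""

import pytest

from delscan import (
    CodingSequence,
    DeletionSpec,
    DualConstruct,
    build_clean_chimera,
    build_library,
    build_repair_template,
    enumerate_deletions,
    grna_min_mismatch,
    load_construct,
    save_construct,
    make_synthetic_construct,
    make_decoy_genome,
    translate,
)
from delscan.design import DEFAULT_PRIMER5, DEFAULT_PRIMER3
from delscan.simdata import DEFAULT_SPACER


def brute_force_intervals(lo, hi):
    return [(m, n) for m in range(lo, hi + 1) for n in range(m, hi + 1)]


class TestEnumerateDeletions:
    def test_87_codon_protein_without_termini_gives_3741(self):
        """86 deletable codons (2..87) give 86*87/2 = 3741 intervals."""
        dels = enumerate_deletions(87, include_termini=False)
        assert len(dels) == 3741
        assert dels[0] == DeletionSpec(2, 2)
        assert dels[-1] == DeletionSpec(87, 87)

    @pytest.mark.parametrize("length", [2, 3, 10, 25, 50, 100])
    def test_matches_brute_force_enumeration(self, length):
        dels = [(d.m, d.n) for d in enumerate_deletions(length)]
        assert dels == brute_force_intervals(2, length)
        k = length - 1
        assert len(dels) == k * (k + 1) // 2

    def test_single_deletable_codon(self):
        assert len(enumerate_deletions(2)) == 1

    def test_ten_deletable_codons_give_55(self):
        assert len(enumerate_deletions(11)) == 55

    def test_termini_included_extends_range_to_stop(self):
        dels = enumerate_deletions(10, include_termini=True)
        assert dels[0] == DeletionSpec(1, 1)
        assert dels[-1] == DeletionSpec(11, 11)  # stop codon deletable
        assert len(dels) == 11 * 12 // 2

    def test_ordering_is_m_then_n(self):
        dels = enumerate_deletions(5)
        assert [(d.m, d.n) for d in dels] == sorted((d.m, d.n) for d in dels)


class TestRepairTemplates:
    def test_default_geometry_is_230_nt(self, toy_construct):
        t = build_repair_template(toy_construct, DeletionSpec(3, 7))
        assert len(t.left_arm) == len(t.right_arm) == 100
        assert len(t.full_seq) == 230

    def test_full_library_all_230(self, toy_construct):
        lib = build_library(toy_construct)
        assert {len(t.full_seq) for t in lib.templates} == {230}
        k = toy_construct.n_codons - 1
        assert len(lib.templates) == k * (k + 1) // 2

    def test_deleted_codons_absent_from_template(self, toy_construct):
        """No base of codons m..n of either allele appears in the oligo."""
        for d in (DeletionSpec(2, 2), DeletionSpec(5, 12), DeletionSpec(2, 20)):
            t = build_repair_template(toy_construct, d)
            # positional: arms end/start exactly at the deletion boundaries
            left_ctx = toy_construct.promoter + toy_construct.allele_up.seq[: 3 * (d.m - 1)]
            right_ctx = (
                toy_construct.allele_down.seq[3 * d.n :] + toy_construct.terminator_flank
            )
            assert t.left_arm == left_ctx[-100:]
            assert t.right_arm == right_ctx[:100]
            # substring search is meaningful once the deleted segment is long
            # enough to be unique (short k-mers recur by chance)
            up = toy_construct.allele_up.seq[3 * (d.m - 1) : 3 * d.n]
            down = toy_construct.allele_down.seq[3 * (d.m - 1) : 3 * d.n]
            if len(up) >= 15:
                assert up not in t.full_seq
                assert down not in t.full_seq
            assert toy_construct.cassette not in t.full_seq

    def test_arm_near_start_fills_from_promoter(self, toy_construct):
        """Deleting from codon 2: left arm = 97 promoter nt + the ATG."""
        t = build_repair_template(toy_construct, DeletionSpec(2, 5))
        assert t.left_arm == toy_construct.promoter[-97:] + toy_construct.allele_up.seq[:3]

    def test_arm_near_end_fills_from_flank(self, toy_construct):
        """Deleting through the last residue: right arm = stop + flank."""
        L = toy_construct.n_codons
        t = build_repair_template(toy_construct, DeletionSpec(3, L))
        stop = toy_construct.allele_down.seq[3 * L :]
        assert t.right_arm == stop + toy_construct.terminator_flank[: 100 - len(stop)]

    def test_implied_junction_translates_to_deleted_protein(self, toy_construct):
        """Repairing with a template yields the wild-type protein minus m..n."""
        wt = toy_construct.protein
        for d in (DeletionSpec(2, 2), DeletionSpec(4, 9), DeletionSpec(10, 20)):
            chimera = (
                toy_construct.allele_up.seq[: 3 * (d.m - 1)]
                + toy_construct.allele_down.seq[3 * d.n :]
            )
            expected = wt[: d.m - 1] + wt[d.n :]
            assert translate(CodingSequence(chimera)).rstrip("*") == expected

    def test_insufficient_flank_is_an_error(self):
        c = make_synthetic_construct(12, seed=3, flank_len=20)
        with pytest.raises(ValueError, match="left arm"):
            build_repair_template(c, DeletionSpec(2, 3))

    def test_clean_chimera_has_no_deletion(self, toy_construct):
        t = build_clean_chimera(toy_construct, junction=8)
        assert t.deletion is None and t.junction == 8
        assert len(t.full_seq) == 230
        core = (
            toy_construct.allele_up.seq[: 3 * 8]
            + toy_construct.allele_down.seq[3 * 8 :]
        )
        assert translate(CodingSequence(core)).rstrip("*") == toy_construct.protein

    def test_library_with_chimeras_deduplicates_them(self, toy_construct):
        plain = build_library(toy_construct)
        with_chim = build_library(toy_construct, include_clean_chimeras=True)
        extra = len(with_chim.templates) - len(plain.templates)
        assert 0 < extra <= toy_construct.n_codons
        seqs = [t.full_seq for t in with_chim.templates if t.deletion is None]
        assert len(seqs) == len(set(seqs))

    def test_engineered_collision_is_flagged_not_merged(self):
        """Identical alleles make symmetric deletions collide; both stay listed."""
        cds = CodingSequence("ATG" + "TGG" * 18 + "TAA")  # Trp-only: recode = identity
        construct = DualConstruct(
            promoter="ACGT" * 40,
            allele_up=cds,
            cassette="CCCCC" + DEFAULT_SPACER + "AGGCCCCC",
            allele_down=cds,
            terminator_flank="TGCA" * 40,
            spacer=DEFAULT_SPACER,
        )
        # with 6-nt arms inside the TGG run, shifting the interval by one
        # codon reproduces the identical oligo
        dels = [DeletionSpec(4, 6), DeletionSpec(5, 7)]
        lib = build_library(construct, dels, arm_len=6)
        assert len(lib.templates) == 2
        assert lib.templates[0].full_seq == lib.templates[1].full_seq
        assert lib.collisions == [("del_4_6", "del_5_7")]

    def test_manifest_and_fasta_round_trip(self, toy_construct, tmp_path):
        from Bio import SeqIO

        lib = build_library(toy_construct)
        fasta = tmp_path / "lib.fa"
        lib.to_fasta(fasta)
        records = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta), "fasta")}
        manifest = lib.manifest()
        assert len(records) == len(manifest)
        for _, row in manifest.iterrows():
            assert records[row["id"]] == row["sequence"]
            assert row["length"] == 230


class TestGrnaMinMismatch:
    def test_exact_site_scores_zero(self):
        genome = "TTTT" + DEFAULT_SPACER + "AGGTTTT"
        assert grna_min_mismatch(DEFAULT_SPACER, genome) == 0

    def test_reverse_strand_site_found(self):
        from Bio.Seq import reverse_complement

        genome = reverse_complement("TTTT" + DEFAULT_SPACER + "AGGTTTT")
        assert grna_min_mismatch(DEFAULT_SPACER, genome) == 0

    def test_no_pam_anywhere_returns_sentinel(self):
        # A/T-only sequence: no GG on either strand
        assert grna_min_mismatch(DEFAULT_SPACER, "ATAT" * 30) is None

    def test_engineered_nearest_site_at_exactly_six(self):
        genome = make_decoy_genome(DEFAULT_SPACER, min_mismatches=6, seed=5)
        assert grna_min_mismatch(DEFAULT_SPACER, genome) == 6

    def test_brute_force_oracle_on_random_genome(self):
        """Min over an explicit scan of every PAM-adjacent 20-mer, both strands."""
        import numpy as np
        from Bio.Seq import reverse_complement

        rng = np.random.default_rng(17)
        genome = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3000)])
        expected = None
        for strand in (genome, reverse_complement(genome)):
            for i in range(len(strand) - 22):
                if strand[i + 21 : i + 23] == "GG":
                    d = sum(
                        a != b for a, b in zip(DEFAULT_SPACER, strand[i : i + 20])
                    )
                    expected = d if expected is None else min(expected, d)
        assert grna_min_mismatch(DEFAULT_SPACER, genome) == expected

    def test_exclude_perfect_skips_on_target(self):
        genome = (
            "TTTT" + DEFAULT_SPACER + "AGG"
            + make_decoy_genome(DEFAULT_SPACER, min_mismatches=6, seed=1)
        )
        assert grna_min_mismatch(DEFAULT_SPACER, genome) == 0
        assert grna_min_mismatch(DEFAULT_SPACER, genome, exclude_perfect=True) == 6

    def test_empty_genome_errors(self):
        with pytest.raises(ValueError, match="empty genome"):
            grna_min_mismatch(DEFAULT_SPACER, [])


def test_construct_yaml_round_trip(toy_construct, tmp_path):
    config = save_construct(toy_construct, tmp_path)
    back = load_construct(config)
    assert back.full_locus == toy_construct.full_locus
    assert back.spacer == toy_construct.spacer
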
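"""Folding contract, structure z-scores, spacer pairing, loop disruption."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from peginsert.core import InsertSequence, PegRNADesign, reverse_complement
from peginsert.structure import (
    DEFAULT_LOOP_COORDS,
    InvalidSequenceError,
    StructureContext,
    fold_mfe,
    loop_disruption,
    spacer_pairing_count,
    structure_zscore,
)


class TestFoldMFE:
    def test_unpairable_sequence_is_unfolded(self):
        res = fold_mfe("AAAAAA")
        assert res.mfe_kcal_mol == 0.0
        assert set(res.structure) == {"."}
        assert all(p == -1 for p in res.pair_table)

    def test_deterministic(self):
        seq = "GGGCUAUUAGCUCAGUUGGUUAGAGCGCACC"
        a, b = fold_mfe(seq), fold_mfe(seq)
        assert a.mfe_kcal_mol == b.mfe_kcal_mol
        assert a.structure == b.structure

    def test_pairing_is_involution(self):
        res = fold_mfe("GGGGGAAAACCCCC" * 2)
        for i, j in enumerate(res.pair_table):
            if j >= 0:
                assert res.pair_table[j] == i and j != i

    def test_hairpin_beats_dinucleotide_shuffle(self):
        stem = "GCGUACGCAGGCUA"
        hairpin = stem + "GAAA" + reverse_complement(
            stem.replace("U", "T")
        ).replace("T", "U")
        rng = np.random.default_rng(7)
        chars = list(hairpin)
        shuffled_mfes = []
        for _ in range(20):
            rng.shuffle(chars)
            shuffled_mfes.append(fold_mfe("".join(chars)).mfe_kcal_mol)
        assert fold_mfe(hairpin).mfe_kcal_mol < min(shuffled_mfes)

    def test_rejects_dna_alphabet(self):
        with pytest.raises(InvalidSequenceError):
            fold_mfe("ACGT")
        with pytest.raises(InvalidSequenceError):
            fold_mfe("")


class TestStructureZScore:
    def test_hairpin_insert_strongly_negative(self, site):
        stem = "GCGTACGCAGGCTA"
        hairpin = stem + "GAAA" + reverse_complement(stem)
        design = PegRNADesign(
            spacer="A" * 20, insert=InsertSequence("h", hairpin),
            homology_arm=site.flank_down[:34],
            pbs=reverse_complement(site.flank_up[-13:]), target_site=site,
        )
        z = structure_zscore(design, StructureContext.INSERT_ONLY,
                             n_background=1000, seed=1)
        assert z.value < -2

    def test_seed_resampling_stability(self, design_for):
        """Background resampling error: for a typical insert (|z| of order
        1) a seed change moves z by far less than 0.15 at n=1000. The
        bound scales with |z| (the sd-estimation term), so extreme-z
        designs are not covered by it."""
        design = design_for("ATGCCTAGAAGTGTGTGATCGCATTGCTGCCA")
        z1 = structure_zscore(design, n_background=1000, seed=1).value
        z2 = structure_zscore(design, n_background=1000, seed=2).value
        assert abs(z1 - z2) < 0.15

    def test_degenerate_background_flagged(self, design_for):
        # 1-nt insert alone: every background MFE is 0
        design = design_for("A")
        z = structure_zscore(design, StructureContext.INSERT_ONLY,
                             n_background=100, seed=0)
        assert z.degenerate and z.value == 0.0

    def test_background_size_floor(self, design_for):
        with pytest.raises(ValueError):
            structure_zscore(design_for("CACGT"), n_background=50)

    def test_z_tracks_structure_strength_at_fixed_length(self, design_for):
        """Within one length, z is monotone in MFE, so it correlates
        negatively with structure strength (-MFE) across designs."""
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        zs, strengths = [], []
        for i in range(60):
            seq = "".join(rng.choice(bases, size=24))
            d = design_for(seq, f"s{i}")
            z = structure_zscore(d, n_background=100, seed=3)
            zs.append(z.value)
            strengths.append(-z.mfe_kcal_mol)
        rho = spearmanr(zs, strengths).statistic
        assert rho < -0.9


class TestSpacerPairing:
    def test_no_complementarity_gives_zero(self, site):
        design = PegRNADesign(
            spacer="A" * 20, insert=InsertSequence("x", "TTT"),
            homology_arm=site.flank_down[:34],
            pbs="T" * 13, target_site=site,
        )
        # insert pegRNA side = AAA, spacer tail = AAA: no A-A pairs
        assert spacer_pairing_count(design) == 0

    def test_full_complement_pairs_three(self, site):
        # spacer tail CCG + scaffold G; insert side must present CGG-complement
        spacer = "A" * 14 + "GGCCCG"
        insert = InsertSequence("x", "CGG" + "ACG")  # pegRNA side starts CGT...
        # first 3 written nt CGG -> pegRNA-side revcomp = CCG pairing CGG region
        design = PegRNADesign(
            spacer=spacer, insert=insert,
            homology_arm=site.flank_down[:34],
            pbs=reverse_complement(site.flank_up[-13:]), target_site=site,
        )
        assert spacer_pairing_count(design) == 3

    def test_short_insert_caps_count(self, site):
        design = PegRNADesign(
            spacer="A" * 20, insert=InsertSequence("x", "T"),
            homology_arm=site.flank_down[:34], pbs="T" * 13, target_site=site,
        )
        assert spacer_pairing_count(design) <= 1


class TestLoopDisruption:
    def test_single_nt_insert_cannot_disrupt(self, design_for):
        assert loop_disruption(design_for("A")) == "none"

    def test_loop1_complement_disrupts(self, design_for):
        """A written insert copying the loop-1 stem sequence yields a
        pegRNA-side insert that is its perfect complement and invades it."""
        design = design_for("ACGT")
        positive = design_for(design.scaffold[8:30], "pos")
        assert loop_disruption(positive) == "loop1"

    def test_random_inserts_rarely_hit_loop1(self, design_for):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        calls = [
            loop_disruption(design_for("".join(rng.choice(bases, size=20)), f"r{i}"))
            for i in range(40)
        ]
        assert calls.count("loop1") < 20

    def test_bad_coordinates_rejected(self, design_for):
        with pytest.raises(ValueError):
            loop_disruption(
                design_for("ACGT"), loop_coords={"loop1": (44, 300),
                                                 "loop2": (59, 70),
                                                 "loop3": (71, 86)}
            )
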
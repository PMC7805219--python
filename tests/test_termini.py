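import numpy as np
import pytest

from tefamkit.errors import ParameterError, TefamkitError
from tefamkit.simulate import simulate_termini_categories
from tefamkit.termini import (
    COMBINED,
    FIVE,
    THREE,
    TerminusPileup,
    build_signature,
    classify_by_termini,
    detect_tsd,
    extract_termini,
    looks_like_solo_ltr,
    render_logo,
    revcomp,
    signature_from_dict,
    signature_to_dict,
)


def _signatures_from(categories, train_frac=1.0, L=60):
    sigs = []
    for cat, fams in sorted(categories.items()):
        n_train = max(2, int(len(fams) * train_frac))
        fives, threes = [], []
        for cons in fams[:n_train]:
            five, three = extract_termini(cons, L)
            fives.append(five)
            threes.append(three)
        sigs.append(build_signature(
            TerminusPileup(cat, FIVE, fives),
            TerminusPileup(cat, THREE, threes),
            make_combined=True,
        ))
    return sigs


class TestExtract:
    def test_long_sequence_slices(self):
        seq = "".join("ACGT"[i % 4] for i in range(100))
        five, three = extract_termini(seq, 60)
        assert five == seq[:60]
        assert three == seq[40:]

    def test_short_sequence_padding(self):
        seq = "ACGT" * 10  # 40 bp
        five, three = extract_termini(seq, 60)
        assert five == seq + "N" * 20
        assert three == "N" * 20 + seq

    def test_empty_sequence_rejected(self):
        with pytest.raises(ParameterError):
            extract_termini("", 60)

    def test_length_outside_stated_range_rejected(self):
        with pytest.raises(ParameterError):
            extract_termini("ACGT" * 30, 20)

    def test_simulated_tir_termini_are_inverted_repeats(self, small_sim):
        """A TIR element's reverse-complemented 3' terminus shares its first
        15 bp with the 5' terminus."""
        _, _, truth = small_sim
        anc = truth.ancestral_sequences["TIRX"]
        five, three = extract_termini(anc, 60)
        rc3 = revcomp(three)
        identity = np.mean([a == b for a, b in zip(five[:15], rc3[:15])])
        assert identity >= 0.8


class TestSignature:
    def test_conserved_column_ic_approaches_two_bits(self):
        rows = ["TA" + "N" * 58] * 4
        sig = build_signature(
            TerminusPileup("c", FIVE, rows),
            TerminusPileup("c", THREE, rows),
            pseudocount=1e-6,
        )
        assert sig.information_content[FIVE][0] == pytest.approx(2.0, abs=1e-3)
        # pseudocounted probability follows the stated formula
        sig2 = build_signature(
            TerminusPileup("c", FIVE, rows),
            TerminusPileup("c", THREE, rows),
            pseudocount=0.5,
        )
        assert sig2.profiles[FIVE][0, 3] == pytest.approx((4 + 0.5) / (4 + 2.0))

    def test_uniform_rows_have_near_zero_information(self, rng):
        rows = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(100)]
        sig = build_signature(
            TerminusPileup("c", FIVE, rows),
            TerminusPileup("c", THREE, rows),
            anchor_offset=0,
        )
        assert abs(sig.information_content[FIVE].mean()) < 0.1

    def test_combined_profile_gains_information_for_palindromic_tir(self, rng):
        """When 5' and RC(3') agree, pooling doubles the evidence: total IC
        of the combined profile exceeds either end's."""
        motif = "".join(rng.choice(list("ACGT"), size=60))
        fives, threes = [], []
        for _ in range(6):
            noisy = list(motif)
            for pos in rng.choice(60, size=6, replace=False):
                noisy[pos] = "ACGT"[int(rng.integers(4))]
            fives.append("".join(noisy))
            noisy3 = list(revcomp(motif))
            for pos in rng.choice(60, size=6, replace=False):
                noisy3[pos] = "ACGT"[int(rng.integers(4))]
            threes.append("".join(noisy3))
        sig = build_signature(
            TerminusPileup("c", FIVE, fives),
            TerminusPileup("c", THREE, threes),
            make_combined=True,
        )
        total = {end: sig.information_content[end].sum()
                 for end in (FIVE, THREE, COMBINED)}
        assert total[COMBINED] > total[FIVE]
        assert total[COMBINED] > total[THREE]

    def test_singleton_pileup_rejected(self):
        with pytest.raises(TefamkitError):
            build_signature(
                TerminusPileup("c", FIVE, ["A" * 60]),
                TerminusPileup("c", THREE, ["A" * 60]),
            )

    def test_mismatched_categories_rejected(self):
        with pytest.raises(ParameterError):
            build_signature(
                TerminusPileup("a", FIVE, ["A" * 60] * 2),
                TerminusPileup("b", THREE, ["A" * 60] * 2),
            )

    def test_serialization_round_trip(self, rng):
        cats = simulate_termini_categories(3, n_categories=1,
                                           families_per_category=4)
        sig = _signatures_from(cats)[0]
        back = signature_from_dict(signature_to_dict(sig))
        assert back.category == sig.category
        for end in sig.profiles:
            assert np.allclose(back.profiles[end], sig.profiles[end])


class TestClassify:
    def test_profile_argmax_query_ranks_its_category_first(self):
        cats = simulate_termini_categories(11, n_categories=3,
                                           families_per_category=6)
        sigs = _signatures_from(cats)
        for sig in sigs:
            five = "".join("ACGT"[i] for i in np.argmax(sig.profiles[FIVE], axis=1))
            three = "".join("ACGT"[i] for i in np.argmax(sig.profiles[THREE], axis=1))
            query = five + "G" * 150 + three
            hits = classify_by_termini(query, sigs)
            assert hits and hits[0].category == sig.category

    def test_training_consensi_self_classify(self):
        cats = simulate_termini_categories(13, n_categories=4,
                                           families_per_category=8)
        sigs = _signatures_from(cats)
        for cat, fams in cats.items():
            for cons in fams[:3]:
                hits = classify_by_termini(cons, sigs)
                assert hits and hits[0].category == cat

    def test_swapped_ends_rejected_by_orientation_filter(self):
        cats = simulate_termini_categories(17, n_categories=2,
                                           families_per_category=6)
        sigs = _signatures_from(cats)
        cat = sigs[0].category
        cons = cats[cat][0]
        five, three = extract_termini(cons, 60)
        swapped = three.replace("N", "") + "G" * 150 + five.replace("N", "")
        hits = classify_by_termini(swapped, sigs)
        assert all(h.category != cat for h in hits)

    def test_reverse_complement_preserves_best_score(self, rng):
        """Strand symmetry on termini with distinct (non-palindromic) ends:
        the RC query flips orientation but keeps the combined score."""
        sigs = []
        queries = {}
        for c in range(3):
            m5 = "".join(rng.choice(list("ACGT"), size=60))
            m3 = "".join(rng.choice(list("ACGT"), size=60))
            fams5, fams3 = [], []
            for _ in range(5):
                noisy5, noisy3 = list(m5), list(m3)
                for pos in rng.choice(60, size=6, replace=False):
                    noisy5[pos] = "ACGT"[int(rng.integers(4))]
                    noisy3[pos] = "ACGT"[int(rng.integers(4))]
                fams5.append("".join(noisy5))
                fams3.append("".join(noisy3))
            sigs.append(build_signature(
                TerminusPileup(f"cat{c}", FIVE, fams5),
                TerminusPileup(f"cat{c}", THREE, fams3),
            ))
            queries[f"cat{c}"] = fams5[0] + "G" * 100 + fams3[0]
        cons = queries["cat0"]
        fwd = classify_by_termini(cons, sigs)
        rev = classify_by_termini(revcomp(cons), sigs)
        assert fwd and rev
        assert fwd[0].category == rev[0].category == "cat0"
        assert fwd[0].score == pytest.approx(rev[0].score, abs=1e-9)
        assert {fwd[0].orientation, rev[0].orientation} == {"+", "-"}

    def test_empty_library_rejected(self):
        with pytest.raises(ParameterError):
            classify_by_termini("ACGT" * 30, [])


class TestTSD:
    def test_exact_five_bp_duplication(self):
        left = "G" * 15 + "ACGTT"
        right = "ACGTT" + "G" * 15
        assert detect_tsd(left, right) == (5, "ACGTT")

    def test_one_mismatch_tolerated_for_long_tsds(self):
        tsd = "ACGTTGCA"  # 8 bp
        mutated = "ACGTTGCT"
        assert detect_tsd("G" * 12 + tsd, mutated + "G" * 12) == (8, tsd)

    def test_no_mismatch_allowed_below_eight(self):
        assert detect_tsd("G" * 15 + "ACGTA", "ACGTT" + "G" * 15) != (5, "ACGTA")

    def test_short_flanks_rejected(self):
        with pytest.raises(ParameterError):
            detect_tsd("ACGT", "ACGT")

    def test_random_flanks_rarely_fake_a_tsd(self, rng):
        """Chance k>=4 duplications on independent 20-bp flanks are rare."""
        false = 0
        for _ in range(1000):
            left = "".join(rng.choice(list("ACGT"), size=20))
            right = "".join(rng.choice(list("ACGT"), size=20))
            hit = detect_tsd(left, right)
            if hit is not None and hit[0] >= 4:
                false += 1
        assert false / 1000 <= 0.05

    def test_recovers_simulated_tsds(self, standard_family_sim):
        """8-bp TSDs flanking simulated insertions are recovered."""
        _, genome, truth = standard_family_sim
        found = total = 0
        for rec in truth.insertions:
            if len(rec.tsd) != 8:
                continue
            left = genome[rec.start - 20 : rec.start]
            right = genome[rec.end : rec.end + 20]
            total += 1
            hit = detect_tsd(left, right)
            if hit is not None and hit[0] == 8:
                found += 1
        assert total >= 40
        assert found / total >= 0.95


class TestSoloLtrHeuristic:
    def test_flags_simulated_solo_ltrs_not_tirs(self):
        from tefamkit.simulate import FamilySpec, SimConfig, simulate

        cfg = SimConfig(seed=3, genome_length=30_000, families=[
            FamilySpec(name="SOLO", kind="solo_ltr", ancestral_length=300,
                       copy_number=5, mean_divergence=0.0, tsd_length=5),
            FamilySpec(name="TIR", kind="class2_tir", ancestral_length=300,
                       copy_number=5, mean_divergence=0.0, tsd_length=8),
        ])
        _, truth = simulate(cfg)
        assert looks_like_solo_ltr(truth.ancestral_sequences["SOLO"], tsd_len=5)
        assert not looks_like_solo_ltr(truth.ancestral_sequences["TIR"], tsd_len=8)


class TestLogo:
    def test_conserved_column_draws_one_tall_letter(self, tmp_path):
        rows = ["TA" + "N" * 58] * 5
        sig = build_signature(
            TerminusPileup("c", FIVE, rows),
            TerminusPileup("c", THREE, rows),
            pseudocount=1e-6,
        )
        out = render_logo(sig, FIVE, tmp_path / "logo.svg")
        text = out.read_text()
        assert text.count('class="logo-col"') == 60
        # column 0 stack: a single T close to 2 bits tall (scale ~ 80/16 = 5)
        first_col = text.split('class="logo-col"')[1]
        assert ">T</text>" in first_col

    def test_uniform_column_draws_near_empty_stack(self, rng, tmp_path):
        rows = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(200)]
        sig = build_signature(
            TerminusPileup("c", FIVE, rows),
            TerminusPileup("c", THREE, rows),
            anchor_offset=0,
        )
        out = render_logo(sig, FIVE, tmp_path / "flat.svg")
        text = out.read_text()
        assert text.count('class="logo-col"') == 60
        # every drawn letter is tiny: vertical scale far below a 2-bit stack
        import re

        scales = [float(s) for s in re.findall(r"scale\(1,([0-9.]+)\)", text)]
        assert scales and max(scales) < 0.3

    def test_missing_end_rejected(self):
        rows = ["A" * 60] * 3
        sig = build_signature(
            TerminusPileup("c", FIVE, rows),
            TerminusPileup("c", THREE, rows),
        )
        with pytest.raises(ParameterError):
            render_logo(sig, COMBINED, "/tmp/never.svg")
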
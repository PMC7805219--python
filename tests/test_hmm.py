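import math

import numpy as np
import pytest

from tefamkit.errors import ParameterError, TefamkitError
from tefamkit.hmm import (
    ProfileHMM,
    build_hmm,
    hmm_from_consensus,
    project_alignment,
    read_hmm,
    scan_sequence,
    viterbi,
    write_hmm,
)
from tefamkit.seed import AlignedInstance, SeedAlignment

BASES = "ACGT"


def random_hmm(L, rng):
    me = rng.dirichlet(np.ones(4), size=L)
    ie = rng.dirichlet(np.ones(4), size=L)
    tm = rng.dirichlet(np.ones(3), size=L)
    t_mm, t_mi, t_md = tm[:, 0].copy(), tm[:, 1].copy(), tm[:, 2].copy()
    ti = rng.dirichlet(np.ones(2), size=L)
    td = rng.dirichlet(np.ones(2), size=L)
    t_im, t_ii = ti[:, 0].copy(), ti[:, 1].copy()
    t_dm, t_dd = td[:, 0].copy(), td[:, 1].copy()
    t_mm[L - 1], t_mi[L - 1], t_md[L - 1] = 1.0, 0.0, 0.0
    t_dm[L - 1], t_dd[L - 1] = 1.0, 0.0
    b = rng.dirichlet(np.ones(2))
    return ProfileHMM(
        name="random", match_emissions=me, insert_emissions=ie,
        t_mm=t_mm, t_mi=t_mi, t_md=t_md, t_im=t_im, t_ii=t_ii,
        t_dm=t_dm, t_dd=t_dd, begin_m=float(b[0]), begin_d=float(b[1]),
    )


def enumerate_best_score(hmm, seq):
    """Independent oracle: exhaustive enumeration of every legal glocal path."""
    n = len(seq)
    code = [BASES.index(c) for c in seq]

    def lg(p):
        return math.log2(p) if p > 0 else -math.inf

    best = -math.inf

    def walk(kind, k, j, score):
        nonlocal best
        if k == hmm.length:
            if kind == "M":
                best = max(best, score + lg(hmm.t_mm[k - 1]))
            elif kind == "D":
                best = max(best, score + lg(hmm.t_dm[k - 1]))
            return
        if kind == "M":
            opts = [("M", lg(hmm.t_mm[k - 1])), ("I", lg(hmm.t_mi[k - 1])),
                    ("D", lg(hmm.t_md[k - 1]))]
        elif kind == "I":
            opts = [("M", lg(hmm.t_im[k - 1])), ("I", lg(hmm.t_ii[k - 1]))]
        else:
            opts = [("M", lg(hmm.t_dm[k - 1])), ("D", lg(hmm.t_dd[k - 1]))]
        for nxt, tc in opts:
            if tc == -math.inf:
                continue
            if nxt == "M" and j < n:
                em = lg(hmm.match_emissions[k, code[j]] / 0.25)
                walk("M", k + 1, j + 1, score + tc + em)
            elif nxt == "I" and j < n:
                em = lg(hmm.insert_emissions[k - 1, code[j]] / 0.25)
                walk("I", k, j + 1, score + tc + em)
            elif nxt == "D":
                walk("D", k + 1, j, score + tc)

    for s in range(n + 1):
        if s < n:
            em = lg(hmm.match_emissions[0, code[s]] / 0.25)
            walk("M", 1, s + 1, lg(hmm.begin_m) + em)
        walk("D", 1, s, lg(hmm.begin_d))
    return best


class TestBuild:
    def test_identical_ungapped_rows(self):
        aln = SeedAlignment("f", [AlignedInstance(f"r{i}", "ACGT") for i in range(4)])
        h = build_hmm(aln)
        assert h.length == 4
        assert [BASES[i] for i in np.argmax(h.match_emissions, axis=1)] == list("ACGT")
        # every interior M->M is the dominant transition
        assert (h.t_mm[:-1] > h.t_mi[:-1]).all() and (h.t_mm[:-1] > h.t_md[:-1]).all()

    def test_half_gapped_column_is_match_at_symfrac_boundary(self):
        aln = SeedAlignment("f", [
            AlignedInstance("r0", "AC"),
            AlignedInstance("r1", "A-"),
        ])
        h = build_hmm(aln, symfrac=0.5)  # occupancy 0.5 >= symfrac: match
        assert h.length == 2

    def test_emission_pseudocount_closed_form(self):
        """(counts + 0.25) / (n + 1) for three rows, pseudocount 1."""
        aln = SeedAlignment("f", [
            AlignedInstance("r0", "AA"),
            AlignedInstance("r1", "AC"),
            AlignedInstance("r2", "CC"),
        ])
        h = build_hmm(aln, pseudocount=1.0)
        assert h.match_emissions[0] == pytest.approx(
            [(2 + 0.25) / 4, (1 + 0.25) / 4, 0.25 / 4, 0.25 / 4]
        )
        assert h.match_emissions[1] == pytest.approx(
            [(1 + 0.25) / 4, (2 + 0.25) / 4, 0.25 / 4, 0.25 / 4]
        )

    def test_zero_match_columns_is_error(self):
        aln = SeedAlignment("f", [
            AlignedInstance("r0", "A---"),
            AlignedInstance("r1", "-C--"),
            AlignedInstance("r2", "--G-"),
        ])
        with pytest.raises(TefamkitError):
            build_hmm(aln, symfrac=0.5)

    def test_probability_conservation_validated_after_build(self, rng):
        for _ in range(5):
            n_rows = int(rng.integers(3, 8))
            n_cols = int(rng.integers(5, 20))
            rows = []
            for r in range(n_rows):
                chars = rng.choice(list("ACGT-"), size=n_cols, p=[0.22] * 4 + [0.12])
                if (chars == "-").all():
                    chars[0] = "A"
                rows.append(AlignedInstance(f"r{r}", "".join(chars)))
            h = build_hmm(SeedAlignment("f", rows))
            h.validate()  # raises on violation

    def test_consensus_map_must_be_injective(self):
        with pytest.raises(ParameterError):
            hmm = hmm_from_consensus("ACGT")
            ProfileHMM(
                name="bad",
                match_emissions=hmm.match_emissions,
                insert_emissions=hmm.insert_emissions,
                t_mm=hmm.t_mm, t_mi=hmm.t_mi, t_md=hmm.t_md,
                t_im=hmm.t_im, t_ii=hmm.t_ii, t_dm=hmm.t_dm, t_dd=hmm.t_dd,
                begin_m=hmm.begin_m, begin_d=hmm.begin_d,
                consensus_map=[0, 0, 1, 2],
            )


class TestViterbi:
    def test_consensus_aligns_all_match(self):
        aln = SeedAlignment("f", [AlignedInstance(f"r{i}", "ACGTACGT")
                                  for i in range(5)])
        h = build_hmm(aln)
        ma = viterbi(h, "ACGTACGT")
        assert [k for k, _, _ in ma.state_path] == ["M"] * 8

    def test_matches_exhaustive_enumeration(self, rng):
        """DP equals brute-force path enumeration on 200 random small
        model/sequence pairs (model <= 4 states, sequence <= 5)."""
        for _ in range(200):
            L = int(rng.integers(1, 5))
            n = int(rng.integers(1, 6))
            h = random_hmm(L, rng)
            seq = "".join(rng.choice(list(BASES), size=n))
            assert viterbi(h, seq).score == pytest.approx(
                enumerate_best_score(h, seq), abs=1e-9
            )

    def test_shuffled_consensus_scores_lower_on_average(self, rng):
        cons = "".join(rng.choice(list(BASES), size=60))
        h = hmm_from_consensus(cons)
        true_score = viterbi(h, cons).score
        shuffled = []
        letters = list(cons)
        for _ in range(100):
            rng.shuffle(letters)
            shuffled.append(viterbi(h, "".join(letters)).score)
        assert np.mean(shuffled) < true_score

    def test_score_invariant_under_background_flanks(self, rng):
        cons = "".join(rng.choice(list(BASES), size=40))
        h = hmm_from_consensus(cons)
        bare = viterbi(h, cons).score
        flank = "".join(rng.choice(list(BASES), size=25))
        flanked = viterbi(h, flank + cons + flank).score
        assert flanked >= bare - 1e-9  # local window at least as good

    def test_n_scores_as_background(self):
        h = hmm_from_consensus("ACGTACGT")
        s_n = viterbi(h, "NNNNNNNN").score
        # all-N emissions contribute 0 bits; score is pure transition cost
        trans = (math.log2(h.begin_m)
                 + sum(math.log2(t) for t in h.t_mm[:-1]) + math.log2(h.t_mm[-1]))
        assert s_n == pytest.approx(trans, abs=1e-9)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ParameterError):
            viterbi(hmm_from_consensus("ACGT"), "")


class TestProjection:
    def test_all_match_projection(self):
        h = hmm_from_consensus("ACGT")
        ma = viterbi(h, "ACGT")
        assert project_alignment(h, ma) == [(0, 0), (1, 1), (2, 2), (3, 3)]

    def test_delete_state_pairs_consensus_with_none(self):
        h = hmm_from_consensus("ACGTA", match_p=0.9)
        ma = viterbi(h, "ACTA")  # G deleted
        pairs = project_alignment(h, ma)
        cons_only = [c for c, s in pairs if s is None]
        assert len(cons_only) == 1

    def test_foreign_alignment_rejected(self):
        h1 = hmm_from_consensus("ACGT")
        h2 = hmm_from_consensus("ACGT")
        ma = viterbi(h1, "ACGT")
        with pytest.raises(ParameterError):
            project_alignment(h2, ma)

    def test_consensus_map_round_trip_identity(self):
        h = hmm_from_consensus("ACGTACGT")
        h.consensus_map = [7, 6, 5, 4, 3, 2, 1, 0]
        inverse = {c: k for k, c in enumerate(h.consensus_map)}
        for k in range(h.length):
            assert inverse[h.consensus_map[k]] == k

    def test_projection_agrees_with_generative_alignment(self, small_sim):
        """>= 95% of projected (consensus, sequence) pairs match the true
        simulated alignment at 10% divergence."""
        from tefamkit.pipeline import build_family_models

        _, _, truth = small_sim
        aln = truth.seed_alignments["TIRX"]
        call, hmm = build_family_models(aln)
        anc_len = len(truth.ancestral_sequences["TIRX"])
        # consensus positions correspond to ancestor positions here: the MSA
        # is ancestor-anchored and every ancestor column is retained
        agree = total = 0
        for rec in truth.insertions[:10]:
            seq = rec.ops.sequence()
            ma = viterbi(hmm, seq)
            proj = {c: s for c, s in project_alignment(hmm, ma)
                    if c is not None and s is not None}
            true_pairs = dict(rec.ops.true_pairs())
            col_of = {c: i for i, c in enumerate(call.column_map)}
            # translate ancestor positions to consensus positions via the MSA
            msa_col_of_anc = _ancestor_columns(truth.seed_alignments["TIRX"], anc_len)
            for anc_pos, seq_pos in true_pairs.items():
                msa_col = msa_col_of_anc[anc_pos]
                if msa_col not in col_of:
                    continue
                total += 1
                if proj.get(col_of[msa_col]) == seq_pos:
                    agree += 1
        assert total > 500
        assert agree / total >= 0.95


def _ancestor_columns(aln, anc_len):
    """MSA column index of each ancestor position (simulator layout: insert
    blocks interleaved with ancestor columns)."""
    # the simulator emits ancestor columns in order; columns in insert
    # blocks have strictly lower occupancy in these small fixtures
    occ = aln.occupancy()
    order = np.argsort(-occ, kind="stable")
    anc_cols = np.sort(order[:anc_len])
    return {i: int(c) for i, c in enumerate(anc_cols)}


class TestScan:
    def test_finds_planted_copies(self, rng):
        cons = "".join(rng.choice(list(BASES), size=80))
        h = hmm_from_consensus(cons)
        seq = ("".join(rng.choice(list(BASES), size=200)) + cons
               + "".join(rng.choice(list(BASES), size=150)) + cons
               + "".join(rng.choice(list(BASES), size=100)))
        hits = scan_sequence(h, seq, min_bits=20)
        starts = sorted(ma.seq_start for ma in hits)
        assert len(hits) == 2
        assert abs(starts[0] - 200) <= 2 and abs(starts[1] - 430) <= 2

    def test_hits_do_not_overlap(self, rng):
        cons = "ACGTACGTGGATCC" * 4
        h = hmm_from_consensus(cons)
        seq = cons * 5
        hits = scan_sequence(h, seq, min_bits=10)
        spans = sorted((ma.seq_start, ma.seq_end) for ma in hits)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2


class TestTextInterchange:
    def test_round_trip_preserves_parameters(self, rng, tmp_path):
        h = random_hmm(6, rng)
        h.consensus_map = [5, 0, 1, 2, 3, 4]
        p = write_hmm(h, tmp_path / "m.hmm")
        h2 = read_hmm(p)
        assert h2.length == 6
        assert h2.consensus_map == h.consensus_map
        assert np.allclose(h2.match_emissions, h.match_emissions, atol=1e-4)
        assert np.allclose(h2.t_mm, h.t_mm, atol=1e-4)
        assert np.allclose(h2.t_dd, h.t_dd, atol=1e-4)
        assert h2.begin_m == pytest.approx(h.begin_m, abs=1e-4)

    def test_not_an_hmm_file_rejected(self, tmp_path):
        p = tmp_path / "junk.hmm"
        p.write_text("not a model\n")
        from tefamkit.errors import FormatError

        with pytest.raises(FormatError):
            read_hmm(p)
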
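"""Profile HMMs built from seed alignments, with consensus correspondence.

The model is a Plan7-like match/insert/delete profile without the multi-hit
(J) loop.  Alignment is *glocal*: global in the model (every match state is
visited or deleted) and local in the sequence (flanking residues are scored
at background, i.e. zero bits).  This matches TE annotation semantics, where
genomic copies are fragments of a full-length family model.

Every match state carries a pointer to the consensus position called from
the same alignment column (``consensus_map``), so alignments produced by the
HMM and by the consensus can be compared position by position.

All scores are log2-odds (bits) against a uniform background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import FormatError, ParameterError, TefamkitError
from .seed import SeedAlignment

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_NEG = -np.inf


@dataclass
class ProfileHMM:
    """Match/insert/delete profile over DNA.

    ``match_emissions``/``insert_emissions`` are (L, 4) probability tables
    (insert state k, 1-based, sits between match k and k+1; row L-1 is
    unused).  Transition arrays are length L, indexed by 0-based match/delete
    state; the last entry of ``t_mm``/``t_dm`` is the exit probability into
    the end state.
    """

    name: str
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    begin_m: float
    begin_d: float
    consensus_map: list[int] = field(default_factory=list)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        L = self.length
        if not self.consensus_map:
            self.consensus_map = list(range(L))
        if len(set(self.consensus_map)) != L:
            raise ParameterError("consensus_map must be injective over match states")
        self.validate()

    @property
    def length(self) -> int:
        return self.match_emissions.shape[0]

    def validate(self, atol: float = 1e-9) -> None:
        """Assert probability conservation for emissions and transitions."""
        L = self.length
        for name, table in (("match", self.match_emissions), ("insert", self.insert_emissions)):
            rows = table if name == "match" else table[: max(L - 1, 0)]
            if rows.size and not np.allclose(rows.sum(axis=1), 1.0, atol=atol):
                raise ParameterError(f"{name} emission rows do not sum to 1")
        if abs(self.begin_m + self.begin_d - 1.0) > atol:
            raise ParameterError("begin transitions do not sum to 1")
        m_out = self.t_mm + self.t_mi + self.t_md
        if not np.allclose(m_out, 1.0, atol=atol):
            raise ParameterError("match-state outgoing transitions do not sum to 1")
        if L > 1:
            i_out = (self.t_im + self.t_ii)[: L - 1]
            if not np.allclose(i_out, 1.0, atol=atol):
                raise ParameterError("insert-state outgoing transitions do not sum to 1")
        d_out = self.t_dm + self.t_dd
        if not np.allclose(d_out, 1.0, atol=atol):
            raise ParameterError("delete-state outgoing transitions do not sum to 1")

    def consensus_sequence(self) -> str:
        """Most likely residue of each match state."""
        return "".join(BASES[i] for i in np.argmax(self.match_emissions, axis=1))


@dataclass
class ModelAlignment:
    """A decoded state path of a sequence through a profile.

    ``state_path`` entries are ``(kind, model_index, sequence_index)`` with
    kind in {'M','I','D'}, 1-based model index, 0-based sequence index
    (``None`` for delete states).
    """

    state_path: list[tuple[str, Optional[int], Optional[int]]]
    score: float
    seq_start: int
    seq_end: int
    hmm: ProfileHMM = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Building
# ---------------------------------------------------------------------------

def build_hmm(
    aln: SeedAlignment,
    symfrac: float = 0.5,
    pseudocount: float = 1.0,
    consensus_positions: Optional[list[int]] = None,
    name: Optional[str] = None,
) -> ProfileHMM:
    """Estimate a profile HMM from a seed alignment.

    Columns with occupancy >= ``symfrac`` (inclusive) become match states.
    Emissions are ``(counts + pseudocount*background) / (total + pseudocount)``
    with a uniform background.  Transitions are counted from each row's
    observed state walk, restricted to the row's covered span so that
    fragment rows do not contribute artificial terminal deletions, and
    Laplace-smoothed (+1 per option).  Sequence weighting is uniform.

    ``consensus_positions`` maps match state k (0-based) to its consensus
    position; by default match state k maps to position k.
    """
    if not (0.0 < symfrac <= 1.0):
        raise ParameterError("symfrac must be in (0, 1]")
    mat = aln.to_matrix()
    n_rows, n_cols = mat.shape
    nongap = mat != "-"
    occ = nongap.mean(axis=0)
    is_match = occ >= symfrac
    match_cols = np.flatnonzero(is_match)
    L = len(match_cols)
    if L == 0:
        raise TefamkitError("no column reaches symfrac occupancy; zero match states")

    bg = 0.25
    m_em = np.zeros((L, 4))
    for k, c in enumerate(match_cols):
        counts = np.array([np.sum(mat[:, c] == b) for b in BASES], dtype=float)
        m_em[k] = (counts + pseudocount * bg) / (counts.sum() + pseudocount)

    # insert emissions pooled over the inter-match column block after match k
    i_em = np.full((L, 4), 0.25)
    # which match state precedes each column (0 = before first match state)
    preceding = np.cumsum(is_match)
    for k in range(1, L):
        block = np.flatnonzero((~is_match) & (preceding == k))
        if len(block) == 0:
            continue
        counts = np.zeros(4)
        for c in block:
            for b in BASES:
                counts[BASE_INDEX[b]] += np.sum(mat[:, c] == b)
        i_em[k - 1] = (counts + pseudocount * bg) / (counts.sum() + pseudocount)

    # transition counts from observed state walks
    c_mm = np.zeros(L); c_mi = np.zeros(L); c_md = np.zeros(L)
    c_im = np.zeros(L); c_ii = np.zeros(L)
    c_dm = np.zeros(L); c_dd = np.zeros(L)
    c_bm = 0.0; c_bd = 0.0
    col_state_idx = {c: k for k, c in enumerate(match_cols)}
    for r in range(n_rows):
        inst = aln.instances[r]
        walk: list[tuple[str, int]] = []  # (kind, 0-based state index)
        for c in range(inst.start_col, inst.end_col):
            if is_match[c]:
                k = col_state_idx[c]
                walk.append(("M" if nongap[r, c] else "D", k))
            elif nongap[r, c]:
                k = int(preceding[c])  # inserts before first match are flanks
                if 1 <= k <= L - 1:
                    walk.append(("I", k - 1))
        if not walk:
            continue
        if walk[0][1] == 0 and walk[0][0] in "MD":
            if walk[0][0] == "M":
                c_bm += 1
            else:
                c_bd += 1
        for (k1, s1), (k2, s2) in zip(walk, walk[1:]):
            if k1 == "M" and k2 == "M":
                c_mm[s1] += 1
            elif k1 == "M" and k2 == "I":
                c_mi[s1] += 1
            elif k1 == "M" and k2 == "D":
                c_md[s1] += 1
            elif k1 == "I" and k2 == "M":
                c_im[s1] += 1
            elif k1 == "I" and k2 == "I":
                c_ii[s1] += 1
            elif k1 == "D" and k2 == "M":
                c_dm[s1] += 1
            elif k1 == "D" and k2 == "D":
                c_dd[s1] += 1
            # I->D and D->I are not modeled (Plan7); such adjacencies are
            # rare artifacts of ragged indel placement and are skipped.

    # Laplace smoothing and normalization
    t_mm = np.ones(L); t_mi = np.zeros(L); t_md = np.zeros(L)
    t_im = np.ones(L); t_ii = np.zeros(L)
    t_dm = np.ones(L); t_dd = np.zeros(L)
    for k in range(L - 1):
        tot = c_mm[k] + c_mi[k] + c_md[k] + 3.0
        t_mm[k] = (c_mm[k] + 1.0) / tot
        t_mi[k] = (c_mi[k] + 1.0) / tot
        t_md[k] = (c_md[k] + 1.0) / tot
        tot = c_im[k] + c_ii[k] + 2.0
        t_im[k] = (c_im[k] + 1.0) / tot
        t_ii[k] = (c_ii[k] + 1.0) / tot
        tot = c_dm[k] + c_dd[k] + 2.0
        t_dm[k] = (c_dm[k] + 1.0) / tot
        t_dd[k] = (c_dd[k] + 1.0) / tot
    # last match/delete state exits to END with probability 1
    t_mm[L - 1] = 1.0; t_mi[L - 1] = 0.0; t_md[L - 1] = 0.0
    t_dm[L - 1] = 1.0; t_dd[L - 1] = 0.0
    begin_m = (c_bm + 1.0) / (c_bm + c_bd + 2.0)
    begin_d = 1.0 - begin_m

    if consensus_positions is None:
        consensus_positions = list(range(L))
    if len(consensus_positions) != L:
        raise ParameterError("consensus_positions length must equal model length")

    return ProfileHMM(
        name=name or aln.family_name,
        match_emissions=m_em,
        insert_emissions=i_em,
        t_mm=t_mm, t_mi=t_mi, t_md=t_md,
        t_im=t_im, t_ii=t_ii,
        t_dm=t_dm, t_dd=t_dd,
        begin_m=begin_m, begin_d=begin_d,
        consensus_map=list(consensus_positions),
    )


def hmm_from_consensus(
    consensus: str,
    name: str = "consensus",
    match_p: float = 0.85,
    t_loop: float = 0.98,
    gap_extend: float = 0.4,
) -> ProfileHMM:
    """Bootstrap a profile directly from a consensus sequence.

    Used when no seed alignment exists yet (e.g. gathering instances for a
    raw de novo consensus): each consensus base becomes a match state
    emitting it with probability ``match_p`` (the rest spread uniformly),
    with geometric indel costs.  N positions emit background.
    """
    if not consensus:
        raise ParameterError("empty consensus")
    if not (0.25 < match_p < 1.0):
        raise ParameterError("match_p must be in (0.25, 1)")
    L = len(consensus)
    off = (1.0 - match_p) / 3.0
    m_em = np.full((L, 4), off)
    for k, ch in enumerate(consensus.upper()):
        j = BASE_INDEX.get(ch)
        if j is None:
            m_em[k] = 0.25
        else:
            m_em[k, j] = match_p
    i_em = np.full((L, 4), 0.25)
    open_p = (1.0 - t_loop) / 2.0
    t_mm = np.full(L, t_loop); t_mi = np.full(L, open_p); t_md = np.full(L, open_p)
    t_im = np.full(L, 1.0 - gap_extend); t_ii = np.full(L, gap_extend)
    t_dm = np.full(L, 1.0 - gap_extend); t_dd = np.full(L, gap_extend)
    t_mm[L - 1] = 1.0; t_mi[L - 1] = 0.0; t_md[L - 1] = 0.0
    t_dm[L - 1] = 1.0; t_dd[L - 1] = 0.0
    return ProfileHMM(
        name=name,
        match_emissions=m_em, insert_emissions=i_em,
        t_mm=t_mm, t_mi=t_mi, t_md=t_md,
        t_im=t_im, t_ii=t_ii, t_dm=t_dm, t_dd=t_dd,
        begin_m=0.95, begin_d=0.05,
    )


# ---------------------------------------------------------------------------
# Viterbi decoding
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    idx = np.full(len(seq), -1, dtype=int)
    for i, ch in enumerate(seq.upper()):
        idx[i] = BASE_INDEX.get(ch, -1)  # -1 = N / ambiguous
    return idx


def _log2(x) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log2(x)


def _emission_bits(em: np.ndarray, code: int) -> np.ndarray:
    """Per-state emission log-odds for one residue (0 bits for N)."""
    if code < 0:
        return np.zeros(em.shape[0])
    return _log2(np.maximum(em[:, code], 1e-300) / 0.25)


def _emission_table(em: np.ndarray) -> np.ndarray:
    """(5, L) emission log-odds indexed by residue code (row 4 = N, 0 bits)."""
    L = em.shape[0]
    table = np.zeros((5, L))
    table[:4] = _log2(np.maximum(em.T, 1e-300) / 0.25)
    return table


def viterbi(hmm: ProfileHMM, seq: str) -> ModelAlignment:
    """Best glocal alignment of ``seq`` to the model, with full traceback.

    The model is traversed in full (via deletes where necessary); unaligned
    sequence flanks are free.  N residues score as background (0 bits).
    """
    if not seq:
        raise ParameterError("sequence must be non-empty")
    code = _encode(seq)
    n, L = len(code), hmm.length
    lmm, lmi, lmd = _log2(hmm.t_mm), _log2(hmm.t_mi), _log2(hmm.t_md)
    lim, lii = _log2(hmm.t_im), _log2(hmm.t_ii)
    ldm, ldd = _log2(hmm.t_dm), _log2(hmm.t_dd)
    lbm, lbd = _log2(np.array([hmm.begin_m]))[0], _log2(np.array([hmm.begin_d]))[0]

    VM = np.full((n + 1, L + 1), _NEG)
    VI = np.full((n + 1, L + 1), _NEG)
    VD = np.full((n + 1, L + 1), _NEG)

    def fill_vd(j: int) -> None:
        # entry candidates: B->D1, or M[j,k-1]->D_k; then D->D chain
        entry = np.full(L + 1, _NEG)
        entry[1] = lbd
        if L > 1:
            entry[2:] = VM[j, 1:L] + lmd[0 : L - 1]
        # VD[j,k] = max over e<=k of entry[e] + sum_{m=e..k-1} ldd[m-1]
        cum = np.concatenate(([0.0], np.cumsum(ldd[0 : L - 1])))  # cum[k-1] spans to k
        adj = entry[1:] - cum  # index k-1 for state k
        run = np.maximum.accumulate(adj)
        VD[j, 1:] = run + cum

    em_m_tab = _emission_table(hmm.match_emissions)
    em_i_tab = _emission_table(hmm.insert_emissions)
    code5 = np.where(code < 0, 4, code)
    for j in range(0, n + 1):
        if j == 0:
            fill_vd(0)
            continue
        em_m = em_m_tab[code5[j - 1]]
        em_i = em_i_tab[code5[j - 1]]
        # match
        VM[j, 1] = em_m[0] + lbm
        if L > 1:
            prev = np.stack([
                VM[j - 1, 1:L] + lmm[0 : L - 1],
                VI[j - 1, 1:L] + lim[0 : L - 1],
                VD[j - 1, 1:L] + ldm[0 : L - 1],
            ])
            VM[j, 2:] = em_m[1:] + prev.max(axis=0)
        # insert (states 1..L-1)
        if L > 1:
            VI[j, 1:L] = em_i[0 : L - 1] + np.maximum(
                VM[j - 1, 1:L] + lmi[0 : L - 1],
                VI[j - 1, 1:L] + lii[0 : L - 1],
            )
        # delete (depends on VM of same j)
        fill_vd(j)

    end_m = VM[:, L] + lmm[L - 1]
    end_d = VD[:, L] + ldm[L - 1]
    ends = np.maximum(end_m, end_d)
    j_best = int(np.argmax(ends))
    score = float(ends[j_best])

    # traceback
    tol = 1e-9
    path: list[tuple[str, Optional[int], Optional[int]]] = []
    j, k = j_best, L
    kind = "M" if end_m[j_best] >= end_d[j_best] - tol else "D"
    while True:
        if kind == "M":
            path.append(("M", k, j - 1))
            em = _emission_bits(hmm.match_emissions, code[j - 1])[k - 1]
            target = VM[j, k] - em
            if k == 1:
                break  # came from B
            if abs(target - (VM[j - 1, k - 1] + lmm[k - 2])) <= tol:
                kind = "M"
            elif abs(target - (VI[j - 1, k - 1] + lim[k - 2])) <= tol:
                kind = "I"
            else:
                kind = "D"
            j, k = j - 1, k - 1
        elif kind == "I":
            path.append(("I", k, j - 1))
            em = _emission_bits(hmm.insert_emissions, code[j - 1])[k - 1]
            target = VI[j, k] - em
            if abs(target - (VM[j - 1, k] + lmi[k - 1])) <= tol:
                kind = "M"
            else:
                kind = "I"
            j = j - 1
        else:  # D
            path.append(("D", k, None))
            if k == 1:
                break  # came from B
            if abs(VD[j, k] - (VM[j, k - 1] + lmd[k - 2])) <= tol:
                kind = "M"
            else:
                kind = "D"
            k = k - 1
    path.reverse()
    emitted = [p[2] for p in path if p[2] is not None]
    seq_start = emitted[0] if emitted else 0
    seq_end = emitted[-1] + 1 if emitted else 0
    return ModelAlignment(state_path=path, score=score, seq_start=seq_start,
                          seq_end=seq_end, hmm=hmm)


def project_alignment(
    hmm: ProfileHMM, ma: ModelAlignment
) -> list[tuple[Optional[int], Optional[int]]]:
    """Map a decoded state path to (consensus position, sequence position) pairs.

    Match states pair both coordinates; insert states pair a sequence
    position with no consensus position; delete states the converse.
    """
    if ma.hmm is not hmm:
        raise ParameterError("alignment was produced by a different model")
    out: list[tuple[Optional[int], Optional[int]]] = []
    for kind, k, j in ma.state_path:
        if kind == "M":
            out.append((hmm.consensus_map[k - 1], j))
        elif kind == "I":
            out.append((None, j))
        else:
            out.append((hmm.consensus_map[k - 1], None))
    return out


# ---------------------------------------------------------------------------
# Multi-hit genome scanning (memory-light, for instance gathering)
# ---------------------------------------------------------------------------

def scan_sequence(
    hmm: ProfileHMM,
    seq: str,
    min_bits: float = 10.0,
    max_hits: int = 10000,
) -> list[ModelAlignment]:
    """Find non-overlapping glocal hits of the model in a long sequence.

    A single rolling-row DP computes, for every end position, the best
    completed-alignment score and its start; peaks above ``min_bits`` are
    taken greedily (best first, overlaps skipped) and each hit is re-decoded
    with full traceback on its local window.  Sequence coordinates of the
    returned alignments are absolute.
    """
    code = _encode(seq)
    n, L = len(code), hmm.length
    if n == 0:
        return []
    lmm, lmi, lmd = _log2(hmm.t_mm), _log2(hmm.t_mi), _log2(hmm.t_md)
    lim, lii = _log2(hmm.t_im), _log2(hmm.t_ii)
    ldm, ldd = _log2(hmm.t_dm), _log2(hmm.t_dd)
    lbm = _log2(np.array([hmm.begin_m]))[0]
    lbd = _log2(np.array([hmm.begin_d]))[0]

    vm_prev = np.full(L + 1, _NEG); vi_prev = np.full(L + 1, _NEG)
    vd_prev = np.full(L + 1, _NEG)
    sm_prev = np.zeros(L + 1, dtype=int); si_prev = np.zeros(L + 1, dtype=int)
    sd_prev = np.zeros(L + 1, dtype=int)
    cum = np.concatenate(([0.0], np.cumsum(ldd[0 : L - 1])))

    def vd_row(vm_row, sm_row, j):
        entry = np.full(L + 1, _NEG)
        entry_start = np.full(L + 1, j, dtype=int)
        entry[1] = lbd
        if L > 1:
            entry[2:] = vm_row[1:L] + lmd[0 : L - 1]
            entry_start[2:] = sm_row[1:L]
        adj = entry[1:] - cum
        run = np.maximum.accumulate(adj)
        # running-argmax: positions where the running max was (re)set
        idx = np.maximum.accumulate(np.where(adj >= run, np.arange(L), 0))
        vd = np.empty(L + 1); vd[0] = _NEG
        vd[1:] = run + cum
        sd = np.empty(L + 1, dtype=int); sd[0] = 0
        sd[1:] = entry_start[1:][idx]
        return vd, sd

    vd_prev, sd_prev = vd_row(vm_prev, sm_prev, 0)
    end_score = np.full(n + 1, _NEG)
    end_start = np.zeros(n + 1, dtype=int)
    e0 = max(vm_prev[L] + lmm[L - 1], vd_prev[L] + ldm[L - 1])
    end_score[0] = e0

    em_m_tab = _emission_table(hmm.match_emissions)
    em_i_tab = _emission_table(hmm.insert_emissions)
    code5 = np.where(code < 0, 4, code)
    lmm_i, lim_i, ldm_i = lmm[0 : L - 1], lim[0 : L - 1], ldm[0 : L - 1]
    lmi_i, lii_i = lmi[0 : L - 1], lii[0 : L - 1]
    for j in range(1, n + 1):
        em_m = em_m_tab[code5[j - 1]]
        em_i = em_i_tab[code5[j - 1]]
        vm = np.full(L + 1, _NEG); vi = np.full(L + 1, _NEG)
        sm = np.zeros(L + 1, dtype=int); si = np.zeros(L + 1, dtype=int)
        vm[1] = em_m[0] + lbm
        sm[1] = j - 1
        if L > 1:
            a = vm_prev[1:L] + lmm_i
            b = vi_prev[1:L] + lim_i
            c = vd_prev[1:L] + ldm_i
            ab = np.maximum(a, b)
            best = np.maximum(ab, c)
            vm[2:] = em_m[1:] + best
            sm[2:] = np.where(a >= best, sm_prev[1:L],
                              np.where(b >= best, si_prev[1:L], sd_prev[1:L]))
            ia = vm_prev[1:L] + lmi_i
            ib = vi_prev[1:L] + lii_i
            vi[1:L] = em_i[0 : L - 1] + np.maximum(ia, ib)
            si[1:L] = np.where(ia >= ib, sm_prev[1:L], si_prev[1:L])
        vd, sd = vd_row(vm, sm, j)
        e_m = vm[L] + lmm[L - 1]
        e_d = vd[L] + ldm[L - 1]
        if e_m >= e_d:
            end_score[j], end_start[j] = e_m, sm[L]
        else:
            end_score[j], end_start[j] = e_d, sd[L]
        vm_prev, vi_prev, vd_prev = vm, vi, vd
        sm_prev, si_prev, sd_prev = sm, si, sd

    # greedy non-overlapping peak selection
    order = np.argsort(end_score)[::-1]
    taken: list[tuple[int, int]] = []
    hits: list[ModelAlignment] = []
    for j in order:
        if end_score[j] < min_bits or len(hits) >= max_hits:
            break
        s, e = int(end_start[j]), int(j)
        if e <= s:
            continue
        if any(not (e <= ts or s >= te) for ts, te in taken):
            continue
        window = seq[s:e]
        ma = viterbi(hmm, window)
        # re-anchor to absolute coordinates
        ma.state_path = [
            (kind, k, (None if jj is None else jj + s)) for kind, k, jj in ma.state_path
        ]
        ma.seq_start += s
        ma.seq_end += s
        hits.append(ma)
        taken.append((s, e))
    hits.sort(key=lambda h: h.seq_start)
    return hits


# ---------------------------------------------------------------------------
# Text interchange (HMMER3-like layout; approximate, not bit-compatible)
# ---------------------------------------------------------------------------

def write_hmm(hmm: ProfileHMM, path) -> Path:
    """Serialize in an HMMER3-style text layout.

    The layout mirrors HMMER3's (negative natural-log probabilities, one
    match/insert/transition triplet per state) for interchange, but is not
    guaranteed bit-compatible with hmmbuild output.  A COMAP line preserves
    the consensus correspondence.
    """
    def nl(p: float) -> str:
        return "*" if p <= 0 else f"{-np.log(p):.5f}"

    L = hmm.length
    lines = [
        "HMMER3/f [tefamkit profile; approximate interchange layout]",
        f"NAME  {hmm.name}",
        f"LENG  {L}",
        "ALPH  DNA",
        "COMAP " + " ".join(str(c) for c in hmm.consensus_map),
        "HMM          A        C        G        T",
        "            m->m     m->i     m->d     i->m     i->i     d->m     d->d",
    ]
    lines.append(
        "  COMPO "
        + "  ".join(nl(b) for b in hmm.background)
    )
    bm, bd = hmm.begin_m, hmm.begin_d
    lines.append(f"  BEGIN {nl(bm)}  {nl(bd)}")
    for k in range(L):
        m = "  ".join(nl(p) for p in hmm.match_emissions[k])
        i = "  ".join(nl(p) for p in hmm.insert_emissions[k])
        t = "  ".join(
            nl(p)
            for p in (
                hmm.t_mm[k], hmm.t_mi[k], hmm.t_md[k],
                hmm.t_im[k], hmm.t_ii[k],
                hmm.t_dm[k], hmm.t_dd[k],
            )
        )
        lines.append(f"  {k + 1:6d} {m}")
        lines.append(f"         {i}")
        lines.append(f"         {t}")
    lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def read_hmm(path) -> ProfileHMM:
    """Read a profile written by :func:`write_hmm`."""
    def ex(tok: str) -> float:
        return 0.0 if tok == "*" else float(np.exp(-float(tok)))

    text = Path(path).read_text().splitlines()
    name = "model"
    L = None
    comap: list[int] = []
    begin_m = begin_d = None
    rows: list[list[str]] = []
    in_params = False
    for line in text:
        s = line.strip()
        if s.startswith("NAME"):
            name = s.split(None, 1)[1]
        elif s.startswith("LENG"):
            L = int(s.split()[1])
        elif s.startswith("COMAP"):
            comap = [int(t) for t in s.split()[1:]]
        elif s.startswith("BEGIN"):
            _, a, b = s.split()
            begin_m, begin_d = ex(a), ex(b)
            in_params = True
        elif s.startswith("//"):
            break
        elif in_params and s:
            rows.append(s.split())
    if L is None or begin_m is None:
        raise FormatError(f"{path}: not a tefamkit HMM file")
    if len(rows) != 3 * L:
        raise FormatError(f"{path}: expected {3 * L} parameter rows, got {len(rows)}")
    m_em = np.zeros((L, 4)); i_em = np.zeros((L, 4))
    t = {k: np.zeros(L) for k in ("mm", "mi", "md", "im", "ii", "dm", "dd")}
    for k in range(L):
        mrow, irow, trow = rows[3 * k], rows[3 * k + 1], rows[3 * k + 2]
        m_em[k] = [ex(v) for v in mrow[1:5]]
        i_em[k] = [ex(v) for v in irow[:4]]
        vals = [ex(v) for v in trow[:7]]
        for key, v in zip(("mm", "mi", "md", "im", "ii", "dm", "dd"), vals):
            t[key][k] = v
    # renormalize away the exp/log round-trip noise
    m_em /= m_em.sum(axis=1, keepdims=True)
    i_em /= i_em.sum(axis=1, keepdims=True)
    for trio in (("mm", "mi", "md"), ("dm", "dd")):
        tot = sum(t[key] for key in trio)
        for key in trio:
            t[key] = np.where(tot > 0, t[key] / np.maximum(tot, 1e-300), 0.0)
    tot = t["im"] + t["ii"]
    mask = tot > 0
    t["im"] = np.where(mask, t["im"] / np.maximum(tot, 1e-300), 1.0)
    t["ii"] = np.where(mask, t["ii"] / np.maximum(tot, 1e-300), 0.0)
    bsum = begin_m + begin_d
    return ProfileHMM(
        name=name,
        match_emissions=m_em, insert_emissions=i_em,
        t_mm=t["mm"], t_mi=t["mi"], t_md=t["md"],
        t_im=t["im"], t_ii=t["ii"],
        t_dm=t["dm"], t_dd=t["dd"],
        begin_m=begin_m / bsum, begin_d=begin_d / bsum,
        consensus_map=comap or list(range(L)),
    )
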
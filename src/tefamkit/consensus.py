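"""CpG-aware consensus calling from seed alignments.

TE copies decay neutrally, so the best per-column call is not the majority
base but the ancestral base maximizing a log-odds score under a neutral
substitution model — in mammals that model must carry the strong GC->AT
transition bias and the ~10x elevated C->T / G->A transition rate at CpG
dinucleotides.  A plain majority vote systematically loses ancestral CpG
sites (most copies have decayed them to TG or CA); the caller here adds a
second pass that scores adjacent column pairs jointly for an ancestral CG
dimer under CpG-elevated rates.

Scores are log2-odds (bits) against a uniform 0.25 background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ParameterError, TefamkitError
from .seed import SeedAlignment

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_TRANSITION = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Neutral-substitution log-odds scores, rows = ancestral, cols = observed.

    ``scores`` are bits; ``probs`` keeps the row-stochastic substitution
    probabilities they derive from.  ``cpg_scores``/``cpg_probs`` are the
    CpG-context variant in which the C->T (ancestral C row) and G->A
    (ancestral G row) probabilities are multiplied by
    ``cpg_transition_multiplier`` before renormalization; they drive the
    joint ancestral-CG pass of :func:`call_consensus`.
    """

    scores: np.ndarray
    probs: np.ndarray
    cpg_scores: np.ndarray
    cpg_probs: np.ndarray
    divergence: float
    gc_to_at_bias: float
    cpg_transition_multiplier: float

    def __post_init__(self) -> None:
        for name in ("scores", "cpg_scores"):
            m = getattr(self, name)
            if not np.all(np.isfinite(m)):
                raise ParameterError(f"{name} contains non-finite entries")
        diag = np.diag(self.scores)
        if not np.all(diag[:, None] >= self.scores - 1e-12):
            raise ParameterError(
                "diagonal of the substitution matrix is not the per-row "
                "maximum; divergence/bias combination is out of the model's "
                "valid range"
            )


def _row_probs(divergence: float, bias_ct_ga: float, extra_ct_ga: float = 1.0) -> np.ndarray:
    """Kimura-style substitution probabilities, ts/tv = 2.

    ``bias_ct_ga`` multiplies the C->T and G->A transition probabilities
    (the GC->AT bias); ``extra_ct_ga`` stacks the CpG multiplier on top.
    Rows are renormalized after biasing.
    """
    d = divergence
    p_ts = (2.0 / 3.0) * d     # transitions carry 2/3 of divergence at ts/tv=2
    p_tv = d / 6.0             # each of the two transversions
    P = np.full((4, 4), p_tv)
    for a in range(4):
        P[a, a] = 1.0 - d
        P[a, _TRANSITION[a]] = p_ts
    P[BASE_INDEX["C"], BASE_INDEX["T"]] *= bias_ct_ga * extra_ct_ga
    P[BASE_INDEX["G"], BASE_INDEX["A"]] *= bias_ct_ga * extra_ct_ga
    P /= P.sum(axis=1, keepdims=True)
    return P


def default_matrix(
    divergence: float = 0.2,
    gc_to_at_bias: float = 2.0,
    cpg_multiplier: float = 10.0,
) -> SubstitutionMatrix:
    """Build the default neutral log-odds matrix.

    Parameters
    ----------
    divergence : expected fraction of substituted sites, in (0, 0.6].
    gc_to_at_bias : factor (>= 1) multiplying C->T and G->A transition
        probabilities, modeling the mammalian GC->AT asymmetry.
    cpg_multiplier : factor (>= 1) further elevating C->T / G->A at CpG
        context, used by the joint dimer pass.

    Scores are ``log2(P(obs|anc) / 0.25)``.  In the divergence->0 limit the
    diagonal approaches 2 bits.
    """
    if not (0.0 < divergence <= 0.6):
        raise ParameterError("divergence must be in (0, 0.6]")
    if gc_to_at_bias < 1.0:
        raise ParameterError("gc_to_at_bias must be >= 1")
    if cpg_multiplier < 1.0:
        raise ParameterError("cpg_multiplier must be >= 1")
    P = _row_probs(divergence, gc_to_at_bias)
    Pc = _row_probs(divergence, gc_to_at_bias, cpg_multiplier)
    floor = 1e-12
    scores = np.log2(np.maximum(P, floor) / 0.25)
    cpg_scores = np.log2(np.maximum(Pc, floor) / 0.25)
    return SubstitutionMatrix(
        scores=scores,
        probs=P,
        cpg_scores=cpg_scores,
        cpg_probs=Pc,
        divergence=divergence,
        gc_to_at_bias=gc_to_at_bias,
        cpg_transition_multiplier=cpg_multiplier,
    )


@dataclass
class ColumnProfile:
    """Base counts and occupancy for one alignment column."""

    counts: dict[str, int]
    occupancy: float

    def count_vector(self) -> np.ndarray:
        v = np.zeros(4)
        for b, n in self.counts.items():
            if b in BASE_INDEX:
                v[BASE_INDEX[b]] = n
        return v


@dataclass
class ConsensusCall:
    """A called consensus with provenance back to alignment columns.

    ``column_map[i]`` is the alignment column that consensus position *i*
    was called from; ``cpg_sites`` lists the consensus index of the C of
    each inferred ancestral CpG.
    """

    sequence: str
    per_position_score: list[float]
    cpg_sites: list[int]
    column_map: list[int]

    def __post_init__(self) -> None:
        assert len(self.sequence) == len(self.column_map)
        for i in self.cpg_sites:
            assert self.sequence[i] == "C" and self.sequence[i + 1] == "G"


def call_column(profile: ColumnProfile, matrix: SubstitutionMatrix) -> tuple[str, float]:
    """Best ancestral base for one column: argmax_b sum_obs counts*score[b][obs].

    Ties break in fixed order A < C < G < T.
    """
    v = profile.count_vector()
    if v.sum() == 0:
        raise ParameterError("empty column: no counted residues")
    totals = matrix.scores @ v
    best = int(np.argmax(totals))  # first max wins: A<C<G<T order
    return BASES[best], float(totals[best])


def _dimer_counts(mat: np.ndarray, ci: int, cj: int) -> np.ndarray:
    """4x4 observed-dimer counts over rows with residues at both columns."""
    x = mat[:, ci]
    y = mat[:, cj]
    counts = np.zeros((4, 4))
    for a in BASES:
        for b in BASES:
            counts[BASE_INDEX[a], BASE_INDEX[b]] = np.sum((x == a) & (y == b))
    return counts


def _joint_cg_score(dimers: np.ndarray, matrix: SubstitutionMatrix) -> float:
    """Score of ancestral 'CG' over observed dimer counts.

    Each observed dimer is explained by the better of two routes: the pair
    behaved as an ordinary dinucleotide (plain matrix) or as a hypermutable
    CpG (elevated C->T / G->A rates).  A surviving CG dimer thus scores at
    the plain diagonal — no penalty for not decaying — while TG and CA
    dimers gain from the elevated rates.  The score for an observed dimer is
    capped at that dimer's own ancestral diagonal, so an ancestral CG can at
    best *tie* a perfectly conserved non-CG pair (and the tie rule then
    requires an observed CG): a column pair of identical copies is never
    rewritten.
    """
    C, G = BASE_INDEX["C"], BASE_INDEX["G"]
    plain = matrix.scores[C][:, None] + matrix.scores[G][None, :]
    elevated = matrix.cpg_scores[C][:, None] + matrix.cpg_scores[G][None, :]
    diag = np.diag(matrix.scores)
    own = diag[:, None] + diag[None, :]
    per_dimer = np.minimum(np.maximum(plain, elevated), own)
    return float(np.sum(dimers * per_dimer))


def _best_independent_pair(dimers: np.ndarray, matrix: SubstitutionMatrix) -> float:
    """Best independent two-column score on the same dimer-covered rows."""
    cx = dimers.sum(axis=1)
    cy = dimers.sum(axis=0)
    return float(np.max(matrix.scores @ cx) + np.max(matrix.scores @ cy))


def call_consensus(
    aln: SeedAlignment,
    matrix: SubstitutionMatrix,
    min_occupancy: float = 0.3,
    include_columns: Optional[Sequence[int]] = None,
) -> ConsensusCall:
    """Call a CpG-aware consensus from a seed alignment.

    Columns with occupancy below ``min_occupancy`` (or without any A/C/G/T
    residue) are excluded; ``include_columns`` force-retains specific columns
    regardless (used to keep consensus and HMM match columns in
    correspondence).  After independent per-column calls, adjacent retained
    column pairs are re-scored jointly for an ancestral CG dimer; when the
    joint score beats the two independent calls (ties resolve to CpG when at
    least one CG dimer is actually observed), C,G is emitted and the site
    recorded.
    """
    mat = aln.to_matrix()
    nongap = mat != "-"
    occ = nongap.mean(axis=0)
    counted = np.isin(mat, list(BASES)).sum(axis=0)
    keep = (occ >= min_occupancy) & (counted > 0)
    if include_columns is not None:
        for c in include_columns:
            if counted[c] > 0:
                keep[c] = True
    cols = np.flatnonzero(keep)
    if len(cols) == 0:
        raise TefamkitError(
            "no alignment column passes the occupancy filter; "
            "empty consensus"
        )

    calls: list[str] = []
    scores: list[float] = []
    for c in cols:
        counts = {b: int(np.sum(mat[:, c] == b)) for b in BASES}
        prof = ColumnProfile(counts=counts, occupancy=float(occ[c]))
        base, score = call_column(prof, matrix)
        calls.append(base)
        scores.append(score)

    # CpG pass over consecutive retained columns, left to right
    cpg_sites: list[int] = []
    i = 0
    while i < len(cols) - 1:
        dimers = _dimer_counts(mat, cols[i], cols[i + 1])
        if dimers.sum() == 0:
            i += 1
            continue
        joint = _joint_cg_score(dimers, matrix)
        indep = _best_independent_pair(dimers, matrix)
        cg_observed = dimers[BASE_INDEX["C"], BASE_INDEX["G"]] > 0
        wins = joint > indep + 1e-9
        ties = abs(joint - indep) <= 1e-9
        if wins or (ties and cg_observed):
            calls[i], calls[i + 1] = "C", "G"
            scores[i] = scores[i + 1] = joint / 2.0
            cpg_sites.append(i)
            i += 2
        else:
            i += 1

    return ConsensusCall(
        sequence="".join(calls),
        per_position_score=scores,
        cpg_sites=cpg_sites,
        column_map=[int(c) for c in cols],
    )


def majority_consensus(
    aln: SeedAlignment,
    min_occupancy: float = 0.3,
    return_columns: bool = False,
):
    """Plain per-column majority baseline (ties break A<C<G<T).

    Kept as the reference point that the log-odds/CpG caller is measured
    against: majority voting loses decayed CpG sites.  With
    ``return_columns`` the retained alignment columns are returned too.
    """
    mat = aln.to_matrix()
    occ = (mat != "-").mean(axis=0)
    out = []
    cols = []
    for c in range(mat.shape[1]):
        if occ[c] < min_occupancy:
            continue
        counts = np.array([np.sum(mat[:, c] == b) for b in BASES])
        if counts.sum() == 0:
            continue
        out.append(BASES[int(np.argmax(counts))])
        cols.append(c)
    seq = "".join(out)
    return (seq, cols) if return_columns else seq
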
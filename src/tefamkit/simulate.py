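"""Synthetic TE families, genomes and ground-truth seed alignments.

The generator reproduces the evolutionary structure that TE curation
assumes: class II (DNA transposon) copies decay independently from a single
ancestor (star phylogeny); class I copies descend from an evolving master
lineage and therefore fall into subfamilies sharing co-segregating
diagnostic substitutions.  Neutral decay follows a continuous-time
substitution model with transition/transversion ratio 2, a GC->AT bias
factor on C->T / G->A, and CpG-context transitions elevated by a
configurable multiplier — decaying CpG dinucleotides into TG (plus-strand
C->T) or CA (minus-strand G->A).  Structural features per element kind:
TIR transposons get terminal inverted repeats and fixed-length TSDs; LINEs
get a poly-A tail, variable-length TSDs and geometric 5' truncation; (solo)
LTRs start TG, end CA, carry an AATAAA poly-adenylation signal and 4-6 bp
TSDs.

Branch lengths are calibrated so that ``mean_divergence`` is the *observed*
copy-to-ancestor mismatch fraction at non-CpG sites (multiple hits are
accounted for).  All randomness flows from a single seed; identical seeds
give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

from .errors import ParameterError, TefamkitError
from .seed import AlignedInstance, SeedAlignment, write_stockholm

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMP = str.maketrans("ACGTN", "TGCAN")
_TRANSITION = {0: 2, 2: 0, 1: 3, 3: 1}

KINDS = ("class2_tir", "class1_line", "ltr", "solo_ltr")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class FamilySpec:
    """One simulated family's parameters."""

    name: str
    kind: str = "class2_tir"
    ancestral_length: int = 1000
    copy_number: int = 50
    mean_divergence: float = 0.15
    cpg_multiplier: float = 10.0
    gc_to_at_bias: float = 2.0
    tsd_length: Optional[int] = 8          # None = variable (LINE-style 7-20)
    truncation_p: Optional[float] = None   # geometric 5' truncation parameter
    subfamily_count: int = 1
    indel_rate: float = 0.1                # indels per substitution
    indel_mean_len: float = 1.7
    tir_length: int = 20

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ParameterError(f"unknown family kind {self.kind!r}")
        if not (0.0 <= self.mean_divergence < 0.7):
            raise ParameterError("mean_divergence out of range")
        if self.copy_number < 1 or self.ancestral_length < 50:
            raise ParameterError("copy_number >= 1 and ancestral_length >= 50 required")


@dataclass
class SimConfig:
    seed: int = 0
    genome_length: int = 100_000
    families: list[FamilySpec] = field(default_factory=list)


def default_config(seed: int = 0) -> SimConfig:
    """The default study conditions: five families spanning the element kinds,
    50 copies each, 15% divergence, CpG transitions x10, GC->AT bias x2."""
    fams = [
        FamilySpec(name="TIR-A", kind="class2_tir", tsd_length=8),
        FamilySpec(name="TIR-B", kind="class2_tir", tsd_length=2),
        FamilySpec(name="LINE-A", kind="class1_line", tsd_length=None,
                   truncation_p=0.002, subfamily_count=2),
        FamilySpec(name="LTR-A", kind="ltr", tsd_length=5),
        FamilySpec(name="SOLO-A", kind="solo_ltr", ancestral_length=350,
                   tsd_length=5),
    ]
    return SimConfig(seed=seed, genome_length=120_000, families=fams)


# ---------------------------------------------------------------------------
# Substitution machinery
# ---------------------------------------------------------------------------

def _rate_matrix(bias: float, cpg_mult_c: float = 1.0, cpg_mult_g: float = 1.0) -> np.ndarray:
    """CTMC rates: transversions 1, transitions 4 (ts/tv = 2), with C->T and
    G->A scaled by ``bias`` and optionally by a CpG multiplier per strand."""
    Q = np.ones((4, 4))
    for a in range(4):
        Q[a, _TRANSITION[a]] = 4.0
    Q[BASE_INDEX["C"], BASE_INDEX["T"]] *= bias * cpg_mult_c
    Q[BASE_INDEX["G"], BASE_INDEX["A"]] *= bias * cpg_mult_g
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _calibrate_time(divergence: float, bias: float) -> float:
    """Branch length t such that the expected observed mismatch fraction of
    the non-CpG matrix equals ``divergence`` (uniform ancestor composition)."""
    if divergence <= 0:
        return 0.0
    Q = _rate_matrix(bias)

    def mismatch(t: float) -> float:
        P = expm(Q * t)
        return float(1.0 - np.mean(np.diag(P)))

    return float(brentq(lambda t: mismatch(t) - divergence, 1e-9, 5.0, xtol=1e-10))


def _dimer_rate_matrix(bias: float, cpg_mult: float) -> np.ndarray:
    """16-state rate matrix for a dinucleotide with context-dependent CpG decay.

    In the CG state the C->T (plus-strand) and G->A (minus-strand) rates are
    multiplied by ``cpg_mult``; once either deamination has happened the
    context is destroyed and both positions evolve at normal rates.  Only
    single-position changes have non-zero rate.
    """
    Q1 = _rate_matrix(bias)
    Q = np.zeros((16, 16))
    C, G, T, A = BASE_INDEX["C"], BASE_INDEX["G"], BASE_INDEX["T"], BASE_INDEX["A"]
    for x in range(4):
        for y in range(4):
            s = 4 * x + y
            for x2 in range(4):
                if x2 != x:
                    r = Q1[x, x2]
                    if x == C and y == G and x2 == T:
                        r *= cpg_mult
                    Q[s, 4 * x2 + y] += r
            for y2 in range(4):
                if y2 != y:
                    r = Q1[y, y2]
                    if x == C and y == G and y2 == A:
                        r *= cpg_mult
                    Q[s, 4 * x + y2] += r
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def substitution_probabilities(
    divergence: float, bias: float, cpg_mult: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch substitution probabilities.

    Returns the 4x4 matrix for ordinary positions and the 16-dimensional
    dimer distribution of an ancestral CpG (row 'CG' of the 16-state
    context-dependent process): most decayed CpGs show TG or CA, not TA,
    because the first deamination removes the elevated context.
    """
    t = _calibrate_time(divergence, bias)
    P = expm(_rate_matrix(bias) * t)
    P16 = expm(_dimer_rate_matrix(bias, cpg_mult) * t)
    C, G = BASE_INDEX["C"], BASE_INDEX["G"]
    cpg_dimer = P16[4 * C + G]
    return P, cpg_dimer


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def _encode(seq: str) -> np.ndarray:
    return np.array([BASE_INDEX[c] for c in seq], dtype=int)


def _mutate_substitutions(
    rng: np.random.Generator,
    anc: np.ndarray,
    cpg_c_sites: np.ndarray,
    P: np.ndarray,
    cpg_dimer: np.ndarray,
) -> np.ndarray:
    """Sample a descendant of ``anc`` (encoded).

    Ancestral CpG dimers (C positions listed in ``cpg_c_sites``) are sampled
    jointly from the context-dependent dimer distribution; all other
    positions independently from the ordinary matrix.
    """
    n = len(anc)
    out = np.empty(n, dtype=int)
    in_cpg = np.zeros(n, dtype=bool)
    in_cpg[cpg_c_sites] = True
    in_cpg[cpg_c_sites + 1] = True
    mask = ~in_cpg
    if mask.any():
        u = rng.random(mask.sum())
        cum = np.cumsum(P, axis=1)
        out[mask] = (u[:, None] > cum[anc[mask]]).sum(axis=1)
    if len(cpg_c_sites):
        u = rng.random(len(cpg_c_sites))
        cumd = np.cumsum(cpg_dimer)
        dimers = (u[:, None] > cumd[None, :]).sum(axis=1)
        out[cpg_c_sites] = dimers // 4
        out[cpg_c_sites + 1] = dimers % 4
    return out


@dataclass
class CopyOps:
    """A copy's edit script against its family ancestor.

    ``subs`` is the substituted (encoded) sequence at full ancestor length;
    ``deleted`` flags removed ancestor positions; ``insertions[slot]`` is a
    string inserted before ancestor position ``slot``; ``truncated_5p``
    ancestor positions are absent from the copy's 5' end.
    """

    subs: np.ndarray
    deleted: np.ndarray
    insertions: dict[int, str]
    truncated_5p: int = 0

    def sequence(self) -> str:
        parts = []
        n = len(self.subs)
        for pos in range(self.truncated_5p, n + 1):
            if pos in self.insertions and pos > self.truncated_5p:
                parts.append(self.insertions[pos])
            if pos < n and not self.deleted[pos]:
                parts.append(BASES[self.subs[pos]])
        return "".join(parts)

    def true_pairs(self) -> list[tuple[int, int]]:
        """(ancestor position, copy position) pairs for surviving positions."""
        pairs = []
        cpos = 0
        n = len(self.subs)
        for pos in range(self.truncated_5p, n + 1):
            if pos in self.insertions and pos > self.truncated_5p:
                cpos += len(self.insertions[pos])
            if pos < n and not self.deleted[pos]:
                pairs.append((pos, cpos))
                cpos += 1
        return pairs


def _apply_indels(rng: np.random.Generator, spec: FamilySpec, ops: CopyOps) -> None:
    n = len(ops.subs)
    expected = spec.indel_rate * spec.mean_divergence * n
    k = rng.poisson(expected)
    p_len = 1.0 / spec.indel_mean_len
    for _ in range(k):
        length = int(rng.geometric(p_len))
        pos = int(rng.integers(0, n))
        if rng.random() < 0.5:  # deletion
            ops.deleted[pos : min(pos + length, n)] = True
        else:
            ops.insertions[pos] = ops.insertions.get(pos, "") + _random_seq(rng, length)


# ---------------------------------------------------------------------------
# Ancestor construction per kind
# ---------------------------------------------------------------------------

def _make_ancestor(rng: np.random.Generator, spec: FamilySpec) -> str:
    n = spec.ancestral_length
    if spec.kind == "class2_tir":
        tir = _random_seq(rng, spec.tir_length)
        core = _random_seq(rng, n - 2 * spec.tir_length)
        return tir + core + revcomp(tir)
    if spec.kind == "class1_line":
        tail = "A" * 25
        return _random_seq(rng, n - len(tail)) + tail
    if spec.kind == "solo_ltr":
        body = _random_seq(rng, n - 10)
        mid = len(body) * 3 // 4
        return "TG" + body[:mid] + "AATAAA" + body[mid:] + "CA"
    if spec.kind == "ltr":
        ltr_len = min(max(n // 5, 100), n // 2 - 10)
        body = _random_seq(rng, ltr_len - 10)
        mid = len(body) * 3 // 4
        ltr = "TG" + body[:mid] + "AATAAA" + body[mid:] + "CA"
        internal = _random_seq(rng, n - 2 * len(ltr))
        return ltr + internal + ltr
    raise ParameterError(spec.kind)


def _cpg_sites(anc: np.ndarray) -> np.ndarray:
    """C positions of CpG dimers (decay targets on either strand)."""
    is_c = anc[:-1] == BASE_INDEX["C"]
    is_g = anc[1:] == BASE_INDEX["G"]
    return np.flatnonzero(is_c & is_g)


# ---------------------------------------------------------------------------
# Family simulation
# ---------------------------------------------------------------------------

@dataclass
class InsertionRecord:
    family: str
    start: int
    end: int
    strand: str
    subfamily: int
    tsd: str
    ops: CopyOps


@dataclass
class GroundTruth:
    ancestral_sequences: dict[str, str]
    insertions: list[InsertionRecord]
    seed_alignments: dict[str, SeedAlignment]
    subfamily_masters: dict[str, list[str]] = field(default_factory=dict)


def _simulate_copies(rng: np.random.Generator, spec: FamilySpec, anc_str: str) -> tuple[list[CopyOps], list[int]]:
    """Copies plus their subfamily labels.

    Class II: star phylogeny, every copy independent from the ancestor.
    Class I: an evolving master lineage; each subfamily master carries >= 3
    extra diagnostic substitutions shared by all its copies.
    """
    anc = _encode(anc_str)
    P, cpg_dimer = substitution_probabilities(
        spec.mean_divergence, spec.gc_to_at_bias, spec.cpg_multiplier
    )

    star = spec.kind != "class1_line" or spec.subfamily_count <= 1
    n_sub = 1 if star else spec.subfamily_count
    masters = [anc.copy()]
    frozen: list[int] = []
    for s in range(1, n_sub):
        m = masters[-1].copy()
        k_diag = 3 + int(rng.integers(0, 3))
        sites = rng.choice(len(m), size=k_diag, replace=False)
        for pos in sites:
            choices = [b for b in range(4) if b != m[pos]]
            m[pos] = int(rng.choice(choices))
        frozen.extend(int(p) for p in sites)
        masters.append(m)
    frozen_idx = np.array(sorted(set(frozen)), dtype=int)

    copies: list[CopyOps] = []
    labels: list[int] = []
    master_cpg = [_cpg_sites(m) for m in masters]
    for i in range(spec.copy_number):
        sub = i * n_sub // spec.copy_number
        base = masters[sub]
        subs = _mutate_substitutions(rng, base, master_cpg[sub], P, cpg_dimer)
        if len(frozen_idx):
            # diagnostic sites define the subfamily and are held fixed, so
            # they co-segregate perfectly with subfamily membership
            subs[frozen_idx] = base[frozen_idx]
        ops = CopyOps(
            subs=subs,
            deleted=np.zeros(len(anc), dtype=bool),
            insertions={},
        )
        if spec.mean_divergence > 0:
            _apply_indels(rng, spec, ops)
        if spec.truncation_p:
            cut = int(rng.geometric(spec.truncation_p)) - 1
            ops.truncated_5p = min(cut, len(anc) - 50)
        copies.append(ops)
        labels.append(sub)
    return copies, labels


def _family_msa(
    family: str, anc_len: int, copies: list[CopyOps], ids: list[str]
) -> SeedAlignment:
    """Column layout: an insert block (width = max insertion) before each
    ancestor position, then the ancestor position column."""
    ins_width = np.zeros(anc_len + 1, dtype=int)
    for ops in copies:
        for slot, s in ops.insertions.items():
            if slot > ops.truncated_5p:
                ins_width[slot] = max(ins_width[slot], len(s))
    rows = []
    for ops in copies:
        parts = []
        for pos in range(anc_len + 1):
            w = ins_width[pos]
            if w:
                s = ops.insertions.get(pos, "") if pos > ops.truncated_5p else ""
                parts.append(s + "-" * (w - len(s)))
            if pos < anc_len:
                if pos < ops.truncated_5p or ops.deleted[pos]:
                    parts.append("-")
                else:
                    parts.append(BASES[ops.subs[pos]])
        rows.append("".join(parts))
    instances = [AlignedInstance(i, r) for i, r in zip(ids, rows)]
    return SeedAlignment(family_name=family, instances=instances)


def simulate(config: SimConfig) -> tuple[str, GroundTruth]:
    """Generate a genome and full ground truth for every configured family."""
    rng = np.random.default_rng(config.seed)
    ancestors: dict[str, str] = {}
    all_copies: list[tuple[FamilySpec, int, CopyOps, int]] = []  # spec, idx, ops, label
    for spec in config.families:
        anc = _make_ancestor(rng, spec)
        ancestors[spec.name] = anc
        copies, labels = _simulate_copies(rng, spec, anc)
        for i, (ops, lab) in enumerate(zip(copies, labels)):
            all_copies.append((spec, i, ops, lab))

    # insertion sites on the background, non-overlapping by construction
    bg = _random_seq(rng, config.genome_length)
    n_ins = len(all_copies)
    max_tsd = 20
    if n_ins * (max_tsd + 2) > config.genome_length:
        raise TefamkitError(
            f"cannot pack {n_ins} insertions into a {config.genome_length} bp genome"
        )
    sites = np.sort(rng.choice(
        np.arange(max_tsd, config.genome_length - max_tsd),
        size=n_ins, replace=False,
    ))
    order = rng.permutation(n_ins)

    pieces: list[str] = []
    records: list[InsertionRecord] = []
    prev = 0
    offset = 0
    for site, ci in zip(sites, order):
        spec, idx, ops, lab = all_copies[ci]
        if spec.tsd_length is None:
            tsd_len = int(rng.integers(7, 21))
        elif spec.kind in ("ltr", "solo_ltr"):
            tsd_len = int(rng.integers(4, 7))
        else:
            tsd_len = spec.tsd_length
        elem = ops.sequence()
        strand = "+" if rng.random() < 0.5 else "-"
        placed = elem if strand == "+" else revcomp(elem)
        tsd = bg[site : site + tsd_len]
        pieces.append(bg[prev : site + tsd_len])
        start = offset + (site + tsd_len - prev)
        pieces.append(placed)
        records.append(InsertionRecord(
            family=spec.name, start=start, end=start + len(placed),
            strand=strand, subfamily=lab, tsd=tsd, ops=ops,
        ))
        offset = start + len(placed)
        prev = site
    pieces.append(bg[prev:])
    genome = "".join(pieces)

    # per-family seed alignments with genome-anchored instance ids
    per_family: dict[str, list[tuple[int, CopyOps, str]]] = {}
    rec_by_ops = {id(r.ops): r for r in records}
    for spec, idx, ops, lab in all_copies:
        rec = rec_by_ops[id(ops)]
        sid = f"genome:{rec.start}-{rec.end}:{rec.strand}"
        per_family.setdefault(spec.name, []).append((idx, ops, sid))
    seed_alignments = {}
    for spec in config.families:
        items = sorted(per_family[spec.name])
        seed_alignments[spec.name] = _family_msa(
            spec.name, len(ancestors[spec.name]),
            [ops for _, ops, _ in items], [sid for _, _, sid in items],
        )

    truth = GroundTruth(
        ancestral_sequences=ancestors,
        insertions=records,
        seed_alignments=seed_alignments,
    )
    return genome, truth


def ancestor_column_positions(anc_len: int, copies: list[CopyOps]) -> list[int]:
    """MSA column index of each ancestor position for the alignment layout
    produced by the simulator (insert blocks interleaved with ancestor
    columns)."""
    ins_width = np.zeros(anc_len + 1, dtype=int)
    for ops in copies:
        for slot, s in ops.insertions.items():
            if slot > ops.truncated_5p:
                ins_width[slot] = max(ins_width[slot], len(s))
    cols = []
    col = 0
    for pos in range(anc_len):
        col += int(ins_width[pos])
        cols.append(col)
        col += 1
    return cols


def simulate_family(spec: FamilySpec, seed: int) -> tuple[str, SeedAlignment, list[CopyOps]]:
    """Simulate one family's copies and seed alignment without genome
    placement — the fast path for consensus parameter-recovery experiments.

    Returns (ancestor, seed alignment, per-copy edit scripts); instance ids
    are synthetic (``copy<i>``).
    """
    rng = np.random.default_rng(seed)
    anc = _make_ancestor(rng, spec)
    copies, _ = _simulate_copies(rng, spec, anc)
    ids = [f"copy{i}" for i in range(len(copies))]
    aln = _family_msa(spec.name, len(anc), copies, ids)
    return anc, aln, copies


# ---------------------------------------------------------------------------
# Termini-category generator (for signature classification experiments)
# ---------------------------------------------------------------------------

def simulate_termini_categories(
    seed: int,
    n_categories: int = 5,
    families_per_category: int = 20,
    termini_divergence: float = 0.10,
    terminus_length: int = 60,
    core_length: int = 200,
) -> dict[str, list[str]]:
    """Family consensi for ``n_categories`` class II categories.

    Each category has a characteristic terminal-inverted-repeat signal: a
    5' terminus motif and a 3' terminus ending in its reverse complement.
    Families diverge from the category motifs at ``termini_divergence``.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, list[str]] = {}
    P, cpg_dimer = substitution_probabilities(termini_divergence, 1.0, 1.0)
    empty = np.array([], dtype=int)
    for c in range(n_categories):
        motif5 = _random_seq(rng, terminus_length)
        fams = []
        for _ in range(families_per_category):
            five = _mutate_substitutions(rng, _encode(motif5), empty, P, cpg_dimer)
            five_s = "".join(BASES[b] for b in five)
            core = _random_seq(rng, core_length)
            fams.append(five_s + core + revcomp(five_s))
        out[f"TIR_cat{c}"] = fams
    return out


# ---------------------------------------------------------------------------
# Fixture emission
# ---------------------------------------------------------------------------

def emit_fixtures(truth: GroundTruth, genome: str, outdir) -> dict[str, Path]:
    """Write genome FASTA, instance BED, per-family Stockholm seeds, ancestor
    FASTA and a truth TSV.  BED is 0-based half-open with a strand column;
    re-extracting intervals (reverse-complementing '-' rows) reproduces the
    instance sequences exactly."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = outdir / "genome.fa"
    with open(paths["genome"], "w") as fh:
        SeqIO.write([SeqRecord(Seq(genome), id="genome", description="")], fh, "fasta")

    paths["ancestors"] = outdir / "ancestors.fa"
    with open(paths["ancestors"], "w") as fh:
        SeqIO.write(
            [SeqRecord(Seq(s), id=name, description="")
             for name, s in sorted(truth.ancestral_sequences.items())],
            fh, "fasta",
        )

    paths["bed"] = outdir / "instances.bed"
    with open(paths["bed"], "w") as fh:
        for i, rec in enumerate(truth.insertions):
            fh.write(
                f"genome\t{rec.start}\t{rec.end}\t{rec.family}.{i}\t0\t{rec.strand}\n"
            )

    paths["truth"] = outdir / "truth.tsv"
    with open(paths["truth"], "w") as fh:
        fh.write("family\tstart\tend\tstrand\tsubfamily\ttsd\ttruncated_5p\n")
        for rec in truth.insertions:
            fh.write(
                f"{rec.family}\t{rec.start}\t{rec.end}\t{rec.strand}\t"
                f"{rec.subfamily}\t{rec.tsd}\t{rec.ops.truncated_5p}\n"
            )

    for name, aln in truth.seed_alignments.items():
        p = outdir / f"{name}.stk"
        write_stockholm(aln, p)
        paths[f"seed:{name}"] = p
    return paths
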
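# Methods

tefamkit is a curation toolkit for transposable-element (TE) families. Its
central contract is that one curated seed alignment — a multiple alignment of
representative genomic copies — is the single source for *both* of a family's
sequence models: a consensus sequence (for string-based tools) and a profile
HMM (for sensitive probabilistic search), with an explicit positional
correspondence between the two so alignments produced by either can be
compared directly. Around that core sit classification machinery (a
path-string taxonomy and class II termini signatures), a tandem-repeat
import filter, a taxonomy-indexed HDF5 store, and a simulator that generates
ground-truth test data with the evolutionary structure these methods assume.

## Neutral-decay consensus calling

Most TE copies evolve neutrally after insertion, so the consensus question
is an ancestral-state inference, not a vote. For each alignment column the
caller picks the ancestral base `b` maximizing

```
S(b) = sum_obs  n_obs * log2( P(obs | b) / 0.25 )
```

where `P(obs | b)` comes from a Kimura-style substitution model with
transition/transversion ratio 2 over a configurable divergence `d` in
(0, 0.6]. Two asymmetries of mammalian neutral evolution are layered on
top:

* **GC→AT bias** — the C→T and G→A transition probabilities are multiplied
  by `gc_to_at_bias` (default 2.0) before row renormalization. A 50/50 C/T
  column therefore resolves to ancestral C: deamination makes C→T much more
  likely than T→C.
* **CpG hypermutability** — methylated CpG dinucleotides decay to TpG (plus
  strand, C→T) or CpA (minus strand, G→A) roughly an order of magnitude
  faster than other sites (`cpg_multiplier`, default 10.0). A majority or
  even per-column log-odds caller loses most ancestral CpG sites, because
  in old families the majority of copies have decayed each one.

The second pass therefore re-scores every adjacent pair of retained columns
jointly for an ancestral `CG` dimer. Observed dimers are counted over rows
covering both columns; each observed dimer `(x, y)` is scored as

```
s_CG(x,y) = min( max( M[C,x]+M[G,y],  Mc[C,x]+Mc[G,y] ),  M[x,x]+M[y,y] )
```

where `M` is the plain log-odds matrix and `Mc` the CpG-elevated variant
(C→T and G→A multiplied by `cpg_multiplier`, rows renormalized). The inner
`max` lets each copy be explained either as a not-yet-decayed CpG (plain
route — so surviving CG dimers are not penalized) or as a decayed one
(elevated route — so TG and CA observations reward the CpG hypothesis).
The outer cap at the observed dimer's own diagonal guarantees that a column
pair of identical copies can at best *tie* the independent calls, never beat
them; the tie rule (prefer the CpG annotation when at least one CG dimer is
actually observed) then annotates conserved CG dimers — which are, by
definition, CpG dinucleotides — without ever rewriting a non-CG pair. If the
joint score strictly beats the sum of the two independent best calls, `C,G`
is emitted and the site recorded.

Columns below `min_occupancy` (default 0.3) are excluded from the consensus;
this floor is deliberately lower than the HMM's match-state threshold so the
consensus extends into lower-coverage flanks while the probabilistic model
does not.

A plain majority caller (`majority_consensus`) is kept as the measured
baseline.

## Profile HMM

`build_hmm` estimates a Plan7-like DNA profile (match/insert/delete states,
no multi-hit loop) from the seed alignment:

* columns with occupancy ≥ `symfrac` (default 0.5, boundary inclusive)
  become match states;
* emissions are `(counts + pseudocount * 0.25) / (total + pseudocount)`
  against a uniform background;
* transitions are counted from each row's observed state walk restricted to
  the row's covered span — fragment rows are the norm for TE instances, and
  counting outside the span would manufacture fake terminal deletions —
  then Laplace-smoothed (+1 per option);
* sequence weighting is uniform (entropy weighting is a declared
  limitation of this version).

Decoding is *glocal*: global in the model, local in the sequence, which is
the semantics of annotating genomic fragments of a full-length family model.
Flanking residues cost nothing (their log-odds against the uniform
background is zero), N scores as background, and all scores are bits. The
Viterbi implementation is verified against exhaustive path enumeration on
small random models, and a memory-light scanning variant (`scan_sequence`)
finds multiple non-overlapping hits along long sequences with a single
rolling-row pass plus local re-decoding.

The consensus↔model correspondence is built by `build_family_models`: the
consensus retains (at least) every match column, and `consensus_map[k]`
points match state `k` at the consensus position called from its column.
The map survives HMM text serialization (a `COMAP` line in the HMMER3-style
layout, which is an interchange format, not a bit-compatible one).

## Termini signatures

TIR-transposon transposases bind the outermost tens of base pairs of their
element, so related families share terminal motifs even without alignable
bodies. For each classification category the toolkit piles up the first and
last 60 bp of member consensi (N-padded at the element boundary), optionally
pools the 5′ rows with reverse-complemented 3′ rows into a combined TIR
model, and estimates ungapped position probability tables with pseudocounts.
Since the pile-ups are ungapped, match-only profiles are exactly equivalent
to profile HMMs here and simpler. Rows may slide 0–3 bp off the terminus
during building; offsets are chosen greedily to maximize count-weighted
empirical column information (a pseudocounted information content would
paradoxically reward sliding rows off the pile-up, because sparse columns
have inflated pseudocount information).

Classification scores a query's two termini against every signature in both
orientations over placements within ±3 bp, and keeps a category only when
both ends agree in orientation and each clears `min_bits` (default 8 bits,
about one chance hit per 256 placements). This orientation-and-position
filter is what makes such short homologies trustworthy; a query with swapped
ends fails it. Reverse-complementing a query exactly swaps which end matches
which profile and preserves the combined score.

TSD detection returns the longest k ∈ [2, 20] with the last k bases of the
left flank equal to the first k of the right flank (one mismatch tolerated
for k ≥ 8). Structural heuristics flag solo-LTR candidates: TG…CA termini,
an AATAAA poly-adenylation signal, and a 4–6 bp TSD.

## Classification tree

Classifications are full path strings (`Interspersed_Repeat;Unknown`) over
an unranked tree: node labels may be reused in different subtrees, so
resolution always walks the full path, and partial paths name internal
nodes. No rank labels exist anywhere in the API or serialization — ranks
for TEs are not definable in a stable way. The shipped tree is a curated
~65-node skeleton spanning the major eukaryotic divisions (class I
LTR/LINE/SINE and LINE-dependent retroposons; class II cut-and-paste,
rolling-circle and self-synthesizing groups; plus non-TE categories), with
cross-system aliases (RepeatMasker, Repbase, Wicker et al.,
Curcio–Derbyshire) where equivalents exist. Users load their own tree for
anything beyond the skeleton.

## Tandem-repeat import filter

Uncurated libraries are prefiltered by a strict rule: a consensus is dropped
iff more than 80% of it is tandemly repetitive AND its longest stretch of
non-tandem sequence is under 100 bp; both inequalities are strict, so
boundary cases are kept. Detection is a period-bounded self-match scan
(periods ≤ 20 bp, so complex satellites with longer units are deliberately
invisible to the filter): for each period `p`, windows where the smoothed
fraction of `seq[i] == seq[i-p]` reaches 0.8 and that span at least three
repeat units become intervals, trimmed so every interval begins and ends
with a solid run of `max(4, p)` consecutive matches (otherwise smoothing
windows straddling a repeat border drag intervals into unique flanking
sequence). This detector is a functional stand-in for a full tandem-repeat
finder; the contract is the filter rule, not parity with any external tool.

## Family store

The HDF5 store embeds a validated, immutable taxonomy and indexes families
two ways: taxon → accessions and name token → taxa. Root paths are
precomputed at open, making ancestor queries O(depth), and subtree queries
walk a children map; query time is therefore proportional to the result,
not the store size. Accessions follow `D[FR]NNNNNNN.V`; uncurated (DR)
families simply omit curation-grade metadata fields. Exports: FASTA, EMBL
flat entries (1-based coordinates, lineage on OC lines), and concatenated
HMM text. The on-disk layout is this package's own, versioned in a root
attribute.

## Simulator

The simulator generates what the methods assume so that every claim is
testable against known truth:

* **Substitutions** follow a CTMC with transversions at rate 1, transitions
  at 4 (ts/tv = 2), C→T/G→A multiplied by the GC→AT bias. Branch length is
  calibrated (by root-finding on the matrix exponential) so that
  `mean_divergence` is the *observed* copy-to-ancestor mismatch fraction at
  non-CpG sites, multiple hits included.
* **CpG decay** uses an exact 16-state dinucleotide process in which the
  C→T and G→A rates are elevated only while the dimer is still CG; after
  the first deamination the context is destroyed and both positions revert
  to normal rates. Decayed CpGs therefore show TG or CA, rarely TA — the
  signal the consensus caller's dimer pass is built to read.
* **Phylogeny**: class II copies mutate independently from the ancestor
  (star); class I families evolve along a master lineage whose subfamily
  steps introduce 3–5 diagnostic substitutions each. Diagnostic sites are
  held fixed in descendant copies, so they co-segregate perfectly with
  subfamily membership by construction.
* **Structure**: TIR elements carry terminal inverted repeats and
  fixed-length TSDs; LINEs get a poly-A tail, variable 7–20 bp TSDs and
  geometric 5′ truncation; (solo) LTRs start TG, end CA, contain AATAAA and
  get 4–6 bp TSDs. Indels are Poisson in number (0.1 per substitution) with
  geometric lengths (mean 1.7) — enough to exercise the HMM's D/I states.
* **Genome placement** duplicates the target site on both sides of each
  insertion; insertions never nest. Instances land on either strand; seed
  alignment rows are always element-oriented.

What the simulator does **not** emulate: genome background structure (GC
isochores, genes), nested or fragmented insertions beyond 5′ truncation,
horizontal transfer, sequencing error, and alignment error (seed alignments
are ground-truth-anchored, not realigned). Passing tests therefore
demonstrate correctness of the inference given correctly aligned neutral
decay — not robustness to misalignment or non-neutral evolution.

## Validation experiments and problem sizes

`tefamkit.experiments` packages the recovery experiments used by both the
test suite and `scripts/acceptance.py`:

* consensus recovery: 20 replicates of a 1,000-bp class II ancestor, 50
  copies, 15% divergence, CpG ×10 — identity and CpG recovery vs. the
  majority baseline;
* oracle equivalence: 1,000 random column profiles vs. exhaustive argmax;
  200 random tiny models (≤ 4 states) and sequences (≤ 5 bp) vs. full path
  enumeration;
* copy-number scaling: n ∈ {5, 10, 20, 50}, 20 replicates each, at 35%
  divergence — high enough that accuracy differences across n stand above
  replicate noise;
* termini: 5 categories × 20 families, signatures from 80%, held-out top-1
  accuracy and orientation-swap rejection at 10% termini divergence;
* store: 1,000 indexed queries vs. linear scan over a 10,000-family store,
  byte-exact round trip, and a query-time comparison against a 1,000-family
  store at fixed result size;
* TSD: recovery of 8-bp duplications at 60 simulated insertions; false-hit
  rate on 1,000 random flank pairs;
* end-to-end import: the default fixture set (five families spanning the
  element kinds, 50 copies each, ~320-kb genome) plus a satellite decoy.

These sizes were chosen as the smallest at which the statistical claims are
stable; all are configurable upward.

## Numerical choices

* Scores are bits throughout; log-odds floors probabilities at 1e-12.
* Ties: per-column consensus calls break A<C<G<T; CpG-pass ties (|Δ| ≤
  1e-9 bits) resolve to the CpG annotation only when a CG dimer is
  observed; Viterbi traceback prefers M over I over D on exact ties; equal
  bit scores during instance assignment go to the lexicographically smaller
  family name.
* The substitution-matrix constructor rejects parameter combinations whose
  biased, renormalized rows would no longer have the diagonal as the row
  maximum (e.g. divergence near 0.6 with a large bias).
* Degenerate inputs raise typed errors: empty columns, all-gap rows,
  alignments with no match column, empty consensus after the occupancy
  filter, singleton termini pile-ups (a one-row signature is unreliable).

## Known limitations

* No entropy/sequence weighting in HMM estimation; redundant seed rows bias
  emissions.
* HMM text export is HMMER3-like for interchange but not bit-compatible
  with hmmbuild/hmmsearch output, and no E-value calibration is provided —
  bit-score thresholds are the user's responsibility.
* Instance gathering in the import pipeline uses this package's own scanner
  at fixture scale; it is not a genome-scale annotation engine.
* The tandem detector approximates (not reproduces) TRF's scoring model.
* The shipped classification tree is a skeleton, not a complete taxonomy of
  TE diversity.
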
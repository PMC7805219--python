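"""Validation experiments: parameter recovery and self-checks at fixture scale.

Each function runs one experiment end to end on synthetic data with known
ground truth and returns plain numbers, so the same battery backs both the
test suite and the reproduction script.  All randomness flows from the
``seed`` argument.
"""

from __future__ import annotations

import math
import time
from pathlib import Path

import numpy as np

from .consensus import call_consensus, default_matrix, majority_consensus
from .famdb import Family, TaxonNode, create_store, open_store
from .hmm import viterbi
from .pipeline import pipeline_uncurated_import
from .simulate import (
    FamilySpec,
    default_config,
    emit_fixtures,
    simulate,
    simulate_family,
    simulate_termini_categories,
)
from .tandem import import_filter
from .termini import (
    FIVE,
    THREE,
    TerminusPileup,
    build_signature,
    classify_by_termini,
    detect_tsd,
    extract_termini,
)

BASES = "ACGT"


def _cpg_positions(seq: str) -> list[int]:
    return [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]


def _recovery_metrics(
    anc: str,
    called: str,
    called_columns,
    anc_columns,
) -> tuple[float, float]:
    """(ancestor identity, CpG recovery), matched through alignment columns.

    An ancestor position counts as recovered when the consensus retains its
    column and calls the ancestral base; a dropped column is an error.
    """
    base_at = {c: called[i] for i, c in enumerate(called_columns)}
    hits = sum(base_at.get(anc_columns[p]) == anc[p] for p in range(len(anc)))
    identity = hits / len(anc)
    cpg = _cpg_positions(anc)
    if cpg:
        rec = np.mean([
            base_at.get(anc_columns[i]) == "C"
            and base_at.get(anc_columns[i + 1]) == "G"
            for i in cpg
        ])
    else:
        rec = float("nan")
    return float(identity), float(rec)


def consensus_recovery(
    seed: int,
    n_replicates: int = 20,
    copy_number: int = 50,
    divergence: float = 0.15,
    length: int = 1000,
) -> dict[str, float]:
    """CpG-aware consensus vs. majority baseline on star-phylogeny families.

    Returns mean ancestor identity and CpG-dinucleotide recovery for the
    log-odds caller, plus the majority baseline's CpG recovery.
    """
    from .simulate import ancestor_column_positions

    matrix = default_matrix(divergence, 2.0, 10.0)
    idents, recoveries, baselines = [], [], []
    for r in range(n_replicates):
        spec = FamilySpec(name="F", kind="class2_tir", ancestral_length=length,
                          copy_number=copy_number, mean_divergence=divergence)
        anc, aln, copies = simulate_family(spec, seed * 1000 + r)
        anc_cols = ancestor_column_positions(len(anc), copies)
        call = call_consensus(aln, matrix)
        maj, maj_cols = majority_consensus(aln, return_columns=True)
        ident, rec = _recovery_metrics(anc, call.sequence, call.column_map,
                                       anc_cols)
        _, rec_maj = _recovery_metrics(anc, maj, maj_cols, anc_cols)
        idents.append(ident)
        recoveries.append(rec)
        baselines.append(rec_maj)
    return {
        "identity": float(np.mean(idents)),
        "cpg_recovery": float(np.nanmean(recoveries)),
        "majority_cpg_recovery": float(np.nanmean(baselines)),
    }


def copy_number_accuracy(
    seed: int,
    copy_numbers: tuple[int, ...] = (5, 10, 20, 50),
    n_replicates: int = 20,
    divergence: float = 0.35,
    length: int = 1000,
) -> dict[int, float]:
    """Mean consensus-to-ancestor identity as a function of copy number.

    With neutral decay, more copies average out more noise, so accuracy
    should rise monotonically toward the original element.
    """
    from .simulate import ancestor_column_positions

    matrix = default_matrix(divergence, 2.0, 10.0)
    out: dict[int, float] = {}
    for n in copy_numbers:
        vals = []
        for r in range(n_replicates):
            spec = FamilySpec(name="F", kind="class2_tir",
                              ancestral_length=length, copy_number=n,
                              mean_divergence=divergence)
            anc, aln, copies = simulate_family(spec, seed * 10_000 + n * 100 + r)
            anc_cols = ancestor_column_positions(len(anc), copies)
            call = call_consensus(aln, matrix)
            ident, _ = _recovery_metrics(anc, call.sequence, call.column_map,
                                         anc_cols)
            vals.append(ident)
        out[n] = float(np.mean(vals))
    return out


def column_call_oracle_agreement(seed: int, n_trials: int = 1000) -> float:
    """Fraction of random column profiles where the caller matches an
    exhaustive argmax over the four ancestral bases."""
    from .consensus import ColumnProfile, call_column

    rng = np.random.default_rng(seed)
    matrix = default_matrix(0.25, 2.0, 10.0)
    agree = 0
    for _ in range(n_trials):
        counts = rng.integers(0, 30, size=4)
        if counts.sum() == 0:
            counts[0] = 1
        got, got_score = call_column(
            ColumnProfile(dict(zip(BASES, map(int, counts))), 1.0), matrix)
        brute = [sum(counts[o] * matrix.scores[a, o] for o in range(4))
                 for a in range(4)]
        best = max(brute)
        ties = [BASES[a] for a in range(4) if abs(brute[a] - best) <= 1e-9]
        agree += got == ties[0] and abs(got_score - best) <= 1e-9
    return agree / n_trials


def _enumerate_viterbi_score(hmm, seq: str) -> float:
    """Brute-force reference: enumerate every legal glocal path."""
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
                walk("M", k + 1, j + 1,
                     score + tc + lg(hmm.match_emissions[k, code[j]] / 0.25))
            elif nxt == "I" and j < n:
                walk("I", k, j + 1,
                     score + tc + lg(hmm.insert_emissions[k - 1, code[j]] / 0.25))
            elif nxt == "D":
                walk("D", k + 1, j, score + tc)

    for s in range(n + 1):
        if s < n:
            walk("M", 1, s + 1,
                 lg(hmm.begin_m) + lg(hmm.match_emissions[0, code[s]] / 0.25))
        walk("D", 1, s, lg(hmm.begin_d))
    return best


def viterbi_oracle_agreement(seed: int, n_trials: int = 200) -> float:
    """Fraction of random tiny model/sequence pairs where the DP score
    equals exhaustive path enumeration."""
    from .hmm import ProfileHMM

    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_trials):
        L = int(rng.integers(1, 5))
        n = int(rng.integers(1, 6))
        me = rng.dirichlet(np.ones(4), size=L)
        ie = rng.dirichlet(np.ones(4), size=L)
        tm = rng.dirichlet(np.ones(3), size=L)
        ti = rng.dirichlet(np.ones(2), size=L)
        td = rng.dirichlet(np.ones(2), size=L)
        t_mm, t_mi, t_md = tm[:, 0].copy(), tm[:, 1].copy(), tm[:, 2].copy()
        t_im, t_ii = ti[:, 0].copy(), ti[:, 1].copy()
        t_dm, t_dd = td[:, 0].copy(), td[:, 1].copy()
        t_mm[L - 1], t_mi[L - 1], t_md[L - 1] = 1.0, 0.0, 0.0
        t_dm[L - 1], t_dd[L - 1] = 1.0, 0.0
        b = rng.dirichlet(np.ones(2))
        hmm = ProfileHMM(name="r", match_emissions=me, insert_emissions=ie,
                         t_mm=t_mm, t_mi=t_mi, t_md=t_md, t_im=t_im, t_ii=t_ii,
                         t_dm=t_dm, t_dd=t_dd, begin_m=float(b[0]),
                         begin_d=float(b[1]))
        seq = "".join(rng.choice(list(BASES), size=n))
        agree += abs(viterbi(hmm, seq).score
                     - _enumerate_viterbi_score(hmm, seq)) <= 1e-9
    return agree / n_trials


def termini_holdout(
    seed: int,
    n_categories: int = 5,
    families_per_category: int = 20,
    divergence: float = 0.10,
    train_frac: float = 0.8,
) -> dict[str, float]:
    """Held-out termini classification across simulated class II categories.

    Signatures are built from ``train_frac`` of each category's families;
    the rest are classified.  Orientation-swapped versions of the held-out
    queries (3' sequence placed at the 5' end on the same strand) must find
    no consistent hit for their true category.
    """
    cats = simulate_termini_categories(
        seed, n_categories=n_categories,
        families_per_category=families_per_category,
        termini_divergence=divergence,
    )
    sigs = []
    held: list[tuple[str, str]] = []
    for cat, fams in sorted(cats.items()):
        n_train = int(len(fams) * train_frac)
        fives, threes = [], []
        for cons in fams[:n_train]:
            five, three = extract_termini(cons)
            fives.append(five)
            threes.append(three)
        sigs.append(build_signature(
            TerminusPileup(cat, FIVE, fives),
            TerminusPileup(cat, THREE, threes),
            make_combined=True,
        ))
        held.extend((cat, cons) for cons in fams[n_train:])

    top1 = 0
    rejected = 0
    for cat, cons in held:
        hits = classify_by_termini(cons, sigs)
        top1 += bool(hits) and hits[0].category == cat
        five, three = extract_termini(cons)
        core = cons[60:-60]
        swapped = three.replace("N", "") + core + five.replace("N", "")
        s_hits = classify_by_termini(swapped, sigs)
        rejected += all(h.category != cat for h in s_hits)
    return {
        "top1_accuracy": top1 / len(held),
        "swapped_rejection": rejected / len(held),
        "n_held_out": len(held),
    }


def tandem_boundary_suite() -> dict[str, bool]:
    """The import-filter rule on constructed boundary cases."""
    unique = (
        "ACGTAGCTTGACCATGGATCCGTAACGGTCAGTTCAGCATGACGTTCAGGATCTAGCCGA"
        "TCATGGTACGAGTCCAGTAGCATCGGATAGTTCGACCTGAATCGGCATCAGTCGATACGG"
        "ATCCGTTGACAGTCATGCAGTTAGCCGATA"
    )
    return {
        "pure_satellite_dropped": not import_filter("TA" * 200).keep,
        "short_unique_composite_dropped":
            not import_filter(unique[:90] + "AC" * 250).keep,
        "long_unique_composite_kept":
            import_filter(unique + "AC" * 250).keep,
    }


def tsd_recovery(seed: int, n_random_trials: int = 1000) -> dict[str, float]:
    """TSD detection on simulated 8-bp duplications and on random flanks."""
    from .simulate import SimConfig

    cfg = SimConfig(seed=seed, genome_length=80_000, families=[
        FamilySpec(name="F", kind="class2_tir", ancestral_length=500,
                   copy_number=60, mean_divergence=0.1, tsd_length=8)])
    genome, truth = simulate(cfg)
    found = total = 0
    for rec in truth.insertions:
        left = genome[rec.start - 20 : rec.start]
        right = genome[rec.end : rec.end + 20]
        total += 1
        hit = detect_tsd(left, right)
        found += hit is not None and hit[0] == 8
    rng = np.random.default_rng(seed + 1)
    false = 0
    for _ in range(n_random_trials):
        left = "".join(rng.choice(list(BASES), size=20))
        right = "".join(rng.choice(list(BASES), size=20))
        hit = detect_tsd(left, right)
        false += hit is not None and hit[0] >= 4
    return {
        "recovery": found / total,
        "false_rate": false / n_random_trials,
    }


def store_scaling(
    seed: int,
    workdir,
    n_large: int = 10_000,
    n_small: int = 1_000,
    n_queries: int = 1000,
    fixed_result_taxon_families: int = 20,
) -> dict[str, float]:
    """Index-vs-scan equivalence, round-trip fidelity and query scaling.

    Builds two synthetic stores (``n_small`` and ``n_large`` families over
    the same taxonomy), verifies 1,000 indexed queries against a brute-force
    scan on the large store, checks byte-identical consensi after reopening,
    and compares per-query times for a taxon holding the same number of
    families in both stores.
    """
    workdir = Path(workdir)
    rng = np.random.default_rng(seed)
    taxonomy = [TaxonNode(1, 1, "root")]
    for t in range(2, 500):
        taxonomy.append(TaxonNode(t, int(rng.integers(1, t)), f"taxon{t}"))
    probe_taxon = 499  # reserved: same family count in both stores

    def build(path, n_families):
        db = create_store(path, taxonomy)
        fams = []
        for i in range(1, n_families + 1):
            if i <= fixed_result_taxon_families:
                taxa = [probe_taxon]
            else:
                taxa = sorted(set(map(int, rng.integers(1, 499,
                                                        size=rng.integers(1, 4)))))
            seq = "".join(rng.choice(list(BASES), size=60))
            fam = Family(accession=f"DR{i:07d}.1", name=f"fam{i}",
                         consensus=seq, clade_taxa=taxa)
            db.add_family(fam)
            fams.append((fam.accession, seq, taxa))
        db.close()
        return fams

    small_path = workdir / "store_small.h5"
    large_path = workdir / "store_large.h5"
    build(small_path, n_small)
    fams = build(large_path, n_large)

    parent = {t.tax_id: t.parent_id for t in taxonomy}

    def ancestors(t):
        out = set()
        while t != 1:
            t = parent[t]
            out.add(t)
        return out

    children: dict[int, set[int]] = {}
    for t in taxonomy[1:]:
        children.setdefault(t.parent_id, set()).add(t.tax_id)

    def descendants(t):
        out, stack = set(), [t]
        while stack:
            x = stack.pop()
            out.add(x)
            stack.extend(children.get(x, ()))
        return out

    db = open_store(large_path)
    # round-trip fidelity
    roundtrip = all(db.get_family(acc).consensus == seq
                    for acc, seq, _ in fams[:200])
    agree = 0
    for _ in range(n_queries):
        q = int(rng.integers(1, 500))
        inc_a = bool(rng.integers(2))
        inc_d = bool(rng.integers(2))
        targets = {q}
        if inc_a:
            targets |= ancestors(q)
        if inc_d:
            targets |= descendants(q)
        expected = sorted(acc for acc, _, taxa in fams if targets & set(taxa))
        got = [f.accession for f in db.families_for_taxon(
            q, include_ancestors=inc_a, include_descendants=inc_d)]
        agree += got == expected

    def median_query_time(path):
        with open_store(path) as store:
            times = []
            for _ in range(30):
                t0 = time.perf_counter()
                res = store.families_for_taxon(probe_taxon)
                times.append(time.perf_counter() - t0)
                assert len(res) == fixed_result_taxon_families
            return float(np.median(times))

    t_large = median_query_time(large_path)
    db.close()
    t_small = median_query_time(small_path)
    return {
        "query_equivalence": agree / n_queries,
        "roundtrip_exact": float(roundtrip),
        "time_ratio": t_large / max(t_small, 1e-9),
    }


def uncurated_import_end_to_end(seed: int, workdir) -> dict[str, float]:
    """Full import on the default fixture set plus a satellite decoy.

    Returns the fraction of stored families carrying both models, whether
    all seed intervals are disjoint across families, and counts.
    """
    workdir = Path(workdir)
    cfg = default_config(seed)
    genome, truth = simulate(cfg)
    paths = emit_fixtures(truth, genome, workdir / "fixtures")
    lib = workdir / "library.fa"
    with open(lib, "w") as fh:
        for name, anc in sorted(truth.ancestral_sequences.items()):
            fh.write(f">{name}\n{anc}\n")
        fh.write(">SAT1\n" + "TA" * 300 + "\n")
    store_path = workdir / "import.h5"
    result = pipeline_uncurated_import(
        lib, genome_fasta=paths["genome"], store_path=store_path, seed=seed)

    intervals = []
    n_stored = n_both = 0
    with open_store(store_path) as db:
        for acc in db.accessions():
            fam = db.get_family(acc)
            n_stored += 1
            n_both += fam.consensus != "" and fam.hmm is not None
            for sid in fam.metadata.get("seed_instances", []):
                _, span, _ = sid.split(":")
                s, e = map(int, span.split("-"))
                intervals.append((s, e))
    intervals.sort()
    disjoint = all(e1 <= s2 for (_, e1), (s2, _) in zip(intervals, intervals[1:]))
    dropped = int((result.report["filter"] == "drop").sum())
    return {
        "n_stored": n_stored,
        "both_models_fraction": n_both / max(n_stored, 1),
        "intervals_disjoint": float(disjoint),
        "n_dropped_by_filter": dropped,
        "n_intervals": len(intervals),
    }
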
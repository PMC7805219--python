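"""Curation workflows: dual model building and the uncurated-import pipeline.

``build_family_models`` is the contract at the heart of the toolkit: one
seed alignment yields both a CpG-aware consensus and a profile HMM whose
match states point at consensus positions, so alignments produced by either
model can be compared directly.

``pipeline_uncurated_import`` turns a raw de novo consensus library into
stored, uncurated (DR-accessioned) families: tandem-repeat prefilter,
instance gathering by glocal profile alignment against a genome with
single-assignment of intervals, seed-alignment construction, dual model
building, termini-based classification, and persistence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .consensus import ConsensusCall, SubstitutionMatrix, call_consensus, default_matrix
from .errors import TefamkitError
from .famdb import FamilyStore, Family, TaxonNode, create_store, open_store
from .hmm import (
    ModelAlignment,
    ProfileHMM,
    build_hmm,
    hmm_from_consensus,
    scan_sequence,
    viterbi,
)
from .seed import AlignedInstance, SeedAlignment
from .tandem import import_filter
from .termini import TerminiSignature, classify_by_termini, revcomp

log = logging.getLogger(__name__)


def build_family_models(
    aln: SeedAlignment,
    matrix: Optional[SubstitutionMatrix] = None,
    min_occupancy: float = 0.3,
    symfrac: float = 0.5,
    pseudocount: float = 1.0,
) -> tuple[ConsensusCall, ProfileHMM]:
    """Derive consensus and HMM from one seed alignment, in correspondence.

    The consensus keeps every column at or above ``min_occupancy`` *plus*
    every HMM match column (occupancy >= ``symfrac``), so each match state
    always has a consensus position to point at; match state k maps to the
    consensus position called from its alignment column.
    """
    if matrix is None:
        matrix = default_matrix()
    mat = aln.to_matrix()
    occ = (mat != "-").mean(axis=0)
    match_cols = np.flatnonzero(occ >= symfrac)
    call = call_consensus(aln, matrix, min_occupancy=min_occupancy,
                          include_columns=match_cols)
    col_to_pos = {c: i for i, c in enumerate(call.column_map)}
    consensus_positions = [col_to_pos[c] for c in match_cols if c in col_to_pos]
    # a match column lacking any A/C/G/T residue cannot be called; exclude it
    usable = [c for c in match_cols if c in col_to_pos]
    hmm = build_hmm(aln, symfrac=symfrac, pseudocount=pseudocount,
                    consensus_positions=consensus_positions)
    if hmm.length != len(usable):
        raise TefamkitError("match columns and consensus correspondence diverged")
    return call, hmm


def msa_from_hits(
    family_name: str,
    hmm: ProfileHMM,
    hits: list[tuple[str, str, ModelAlignment]],
) -> SeedAlignment:
    """Assemble a seed alignment from model alignments of gathered instances.

    ``hits`` are (source_id, oriented_sequence, alignment) triples whose
    alignments come from ``hmm``.  Columns are the model's match states plus
    an insert block between consecutive states sized by the longest observed
    insertion.
    """
    L = hmm.length
    ins_width = np.zeros(L + 1, dtype=int)
    parsed = []
    for source_id, seq, ma in hits:
        cells: dict[int, str] = {}
        inserts: dict[int, str] = {}
        last_m = 0
        for kind, k, j in ma.state_path:
            if kind == "M":
                cells[k] = seq[j]
                last_m = k
            elif kind == "D":
                cells[k] = "-"
                last_m = k
            else:  # insert after current match state
                inserts[last_m] = inserts.get(last_m, "") + seq[j]
        for slot, s in inserts.items():
            ins_width[slot] = max(ins_width[slot], len(s))
        parsed.append((source_id, cells, inserts))
    rows = []
    for source_id, cells, inserts in parsed:
        covered = [k for k, v in cells.items() if v != "-"]
        lo, hi = (min(covered), max(covered)) if covered else (1, 0)
        parts = []
        for k in range(0, L + 1):
            if k > 0:
                parts.append(cells.get(k, "-") if lo <= k <= hi else "-")
            w = ins_width[k]
            if w:
                s = inserts.get(k, "")
                parts.append(s + "-" * (w - len(s)))
        rows.append(AlignedInstance(source_id, "".join(parts)))
    return SeedAlignment(family_name=family_name, instances=rows)


@dataclass
class ImportResult:
    report: pd.DataFrame
    accessions: dict[str, str] = field(default_factory=dict)


def _read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def pipeline_uncurated_import(
    library_fasta,
    genome_fasta=None,
    store_path=None,
    signature_library: Optional[list[TerminiSignature]] = None,
    matrix: Optional[SubstitutionMatrix] = None,
    min_bits: float = 25.0,
    min_instances: int = 2,
    clade_taxa: Optional[list[int]] = None,
    seed: int = 0,
) -> ImportResult:
    """Import an uncurated consensus library as DR families.

    Per library entry: (1) tandem-repeat import filter; (2) when a genome is
    supplied, instances are gathered by glocal profile alignment of every
    family model against both genome strands, and each genome interval is
    assigned only to its best-scoring family (ties to the lexicographically
    smaller family name); (3) a seed alignment is built from the assigned
    instances and both models are re-derived from it; (4) termini
    classification against a signature library when one is given; (5) the
    family is stored with a fresh DR accession.  Per-family failures are
    logged and skipped; the batch never aborts.  The returned report has one
    row per library entry recording every decision.
    """
    if matrix is None:
        matrix = default_matrix()
    entries = _read_fasta(library_fasta)
    genome = None
    if genome_fasta is not None:
        genome = "".join(seq for _, seq in _read_fasta(genome_fasta))

    if store_path is not None:
        p = Path(store_path)
        if p.exists():
            store: Optional[FamilyStore] = open_store(p, "r+")
        else:
            store = create_store(p, [TaxonNode(1, 1, "root", "no rank")])
    else:
        store = None
    taxa = clade_taxa if clade_taxa is not None else ([1] if store else [])

    rows = []
    accessions: dict[str, str] = {}
    kept: list[tuple[str, str]] = []
    for name, cons in entries:
        decision = import_filter(cons)
        row = {
            "family": name,
            "tandem_fraction": round(decision.tandem_fraction, 4),
            "longest_clear_run": decision.longest_clear_run,
            "filter": "keep" if decision.keep else "drop",
            "n_instances": 0,
            "accession": "",
            "classification": "",
            "status": "",
        }
        if not decision.keep:
            row["status"] = "dropped: " + "; ".join(decision.reasons)
            rows.append(row)
            continue
        kept.append((name, cons))
        rows.append(row)
    row_by_name = {r["family"]: r for r in rows}

    # bootstrap models and instance gathering
    assignments: dict[str, list[tuple[str, str, ModelAlignment]]] = {}
    boot: dict[str, ProfileHMM] = {}
    if genome is not None:
        all_hits = []  # (score, family, start, end, strand)
        for name, cons in kept:
            boot[name] = hmm_from_consensus(cons, name=name)
            for strand, target in (("+", genome), ("-", revcomp(genome))):
                for ma in scan_sequence(boot[name], target, min_bits=min_bits):
                    if strand == "+":
                        s, e = ma.seq_start, ma.seq_end
                    else:
                        s, e = len(genome) - ma.seq_end, len(genome) - ma.seq_start
                    all_hits.append((ma.score, name, s, e, strand))
        # single assignment: best score first; ties to smaller family name
        all_hits.sort(key=lambda h: (-h[0], h[1], h[2]))
        taken: list[tuple[int, int]] = []
        for score, name, s, e, strand in all_hits:
            if any(not (e <= ts or s >= te) for ts, te in taken):
                continue
            taken.append((s, e))
            seq = genome[s:e] if strand == "+" else revcomp(genome[s:e])
            sid = f"genome:{s}-{e}:{strand}"
            ma = viterbi(boot[name], seq)
            assignments.setdefault(name, []).append((sid, seq, ma))

    for name, cons in kept:
        row = row_by_name[name]
        try:
            if genome is not None:
                hits = assignments.get(name, [])
                row["n_instances"] = len(hits)
                if len(hits) < min_instances:
                    row["status"] = f"skipped: {len(hits)} instance(s) found"
                    continue
                aln = msa_from_hits(name, boot[name], sorted(hits))
            else:
                aln = SeedAlignment(name, [AlignedInstance(name, cons)])
                row["n_instances"] = 1
            call, hmm = build_family_models(aln, matrix)
            classification = "Interspersed_Repeat;Unknown"
            if signature_library:
                termini_hits = classify_by_termini(call.sequence, signature_library)
                if termini_hits:
                    classification = termini_hits[0].category
            row["classification"] = classification
            if store is not None:
                fam = Family(
                    accession=store.next_accession(),
                    name=name,
                    consensus=call.sequence,
                    classification=classification,
                    clade_taxa=taxa,
                    curated=False,
                    hmm=hmm,
                    metadata={
                        "description": "uncurated de novo family import",
                        "n_seed_instances": row["n_instances"],
                        "seed_instances": [i.source_id for i in aln.instances],
                        "cpg_sites": len(call.cpg_sites),
                        "seed": seed,
                    },
                )
                accessions[name] = store.add_family(fam)
                row["accession"] = accessions[name]
            row["status"] = "stored" if store is not None else "processed"
        except TefamkitError as exc:
            log.warning("family %s failed: %s", name, exc)
            row["status"] = f"failed: {exc}"
    if store is not None:
        store.close()
    report = pd.DataFrame(rows)
    return ImportResult(report=report, accessions=accessions)
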
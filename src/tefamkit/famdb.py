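"""Taxonomy-indexed HDF5 store for TE families.

The store holds family consensi, serialized profile HMMs, metadata, an
embedded taxonomy, and two indexes — taxon -> family accessions and
name-token -> taxon ids — so that offline queries ("all families for taxon
X, with ancestors/descendants") run in time proportional to the result, not
the database size.  Root paths through the taxonomy are precomputed at open
(the taxonomy is immutable per store), making ancestor queries O(depth).

Accessions follow the DF (curated) / DR (uncurated) scheme with a version
suffix, e.g. ``DR0086957.1``.  Uncurated families simply omit
curation-grade metadata fields rather than storing nulls.

The container layout is this package's own, versioned in a root attribute;
it honors the offline/indexed/taxonomy-aware contract rather than any
external byte format.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import h5py
import numpy as np

from .errors import FormatError, LookupFailure, ParameterError
from .hmm import ProfileHMM

LAYOUT_VERSION = "tefamkit-famdb-1"
ACCESSION_RE = re.compile(r"^D[FR][0-9]{7}\.[0-9]+$")


@dataclass
class TaxonNode:
    """One node of an NCBI-taxonomy-like tree.  ``rank`` is informational only."""

    tax_id: int
    parent_id: int
    name: str
    rank: str = ""


@dataclass
class Family:
    """A TE family: models, classification, clade labels, metadata."""

    accession: str
    name: str
    consensus: str
    classification: str = "Interspersed_Repeat;Unknown"
    clade_taxa: list[int] = field(default_factory=list)
    curated: bool = False
    hmm: Optional[ProfileHMM] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not ACCESSION_RE.match(self.accession):
            raise ParameterError(
                f"accession {self.accession!r} does not match the DF/DR scheme"
            )
        expected = "DF" if self.curated else "DR"
        if not self.accession.startswith(expected):
            raise ParameterError(
                f"accession prefix of {self.accession!r} inconsistent with "
                f"curated={self.curated}"
            )
        if not self.consensus:
            raise ParameterError("family consensus must be non-empty")


def _hmm_to_json(h: ProfileHMM) -> str:
    return json.dumps({
        "name": h.name,
        "match_emissions": h.match_emissions.tolist(),
        "insert_emissions": h.insert_emissions.tolist(),
        "t_mm": h.t_mm.tolist(), "t_mi": h.t_mi.tolist(), "t_md": h.t_md.tolist(),
        "t_im": h.t_im.tolist(), "t_ii": h.t_ii.tolist(),
        "t_dm": h.t_dm.tolist(), "t_dd": h.t_dd.tolist(),
        "begin_m": h.begin_m, "begin_d": h.begin_d,
        "consensus_map": h.consensus_map,
    })


def _hmm_from_json(text: str) -> ProfileHMM:
    d = json.loads(text)
    return ProfileHMM(
        name=d["name"],
        match_emissions=np.array(d["match_emissions"]),
        insert_emissions=np.array(d["insert_emissions"]),
        t_mm=np.array(d["t_mm"]), t_mi=np.array(d["t_mi"]), t_md=np.array(d["t_md"]),
        t_im=np.array(d["t_im"]), t_ii=np.array(d["t_ii"]),
        t_dm=np.array(d["t_dm"]), t_dd=np.array(d["t_dd"]),
        begin_m=d["begin_m"], begin_d=d["begin_d"],
        consensus_map=d["consensus_map"],
    )


def _validate_taxonomy(taxonomy: list[TaxonNode]) -> int:
    ids = {t.tax_id for t in taxonomy}
    if len(ids) != len(taxonomy):
        raise ParameterError("duplicate tax_ids in taxonomy")
    roots = [t for t in taxonomy if t.parent_id == t.tax_id or t.parent_id == 0]
    if len(roots) != 1:
        raise ParameterError(f"taxonomy must have exactly one root, found {len(roots)}")
    root = roots[0]
    parent = {t.tax_id: t.parent_id for t in taxonomy}
    for t in taxonomy:
        if t.tax_id != root.tax_id and t.parent_id not in ids:
            raise ParameterError(f"taxon {t.tax_id} has unknown parent {t.parent_id}")
    resolved: set[int] = {root.tax_id}
    for t in taxonomy:
        seen: set[int] = set()
        node = t.tax_id
        while node not in resolved:
            if node in seen:
                raise ParameterError(f"taxonomy cycle involving taxon {node}")
            seen.add(node)
            node = parent[node]
        resolved.update(seen)
    return root.tax_id


class FamilyStore:
    """An open family store.  Use :func:`create_store` / :func:`open_store`."""

    def __init__(self, h5: h5py.File, mode: str):
        self._h5 = h5
        self._mode = mode
        self._load_taxonomy()
        self._load_index()

    # -- lifecycle ----------------------------------------------------------

    def close(self) -> None:
        if self._mode != "r":
            self.flush()
        self._h5.close()

    def flush(self) -> None:
        self._write_index()
        self._h5.flush()

    def __enter__(self) -> "FamilyStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- taxonomy -----------------------------------------------------------

    def _load_taxonomy(self) -> None:
        g = self._h5["taxonomy"]
        tax_ids = g["tax_id"][:]
        parents = g["parent_id"][:]
        names = [n.decode() for n in g["name"][:]]
        ranks = [r.decode() for r in g["rank"][:]]
        self._taxa = {
            int(t): TaxonNode(int(t), int(p), n, r)
            for t, p, n, r in zip(tax_ids, parents, names, ranks)
        }
        self._root_id = int(self._h5.attrs["taxonomy_root"])
        self._children: dict[int, list[int]] = {}
        for t in self._taxa.values():
            if t.tax_id != self._root_id:
                self._children.setdefault(t.parent_id, []).append(t.tax_id)
        # precomputed root paths: ancestor queries are O(depth)
        self._ancestors: dict[int, tuple[int, ...]] = {}
        for tid in self._taxa:
            path = []
            node = tid
            while node != self._root_id:
                node = self._taxa[node].parent_id
                path.append(node)
            self._ancestors[tid] = tuple(path)

    def taxon(self, tax_id: int) -> TaxonNode:
        try:
            return self._taxa[int(tax_id)]
        except KeyError:
            raise LookupFailure(f"unknown taxon {tax_id}") from None

    def lineage(self, tax_id: int) -> list[TaxonNode]:
        """Root-to-taxon list of nodes."""
        self.taxon(tax_id)
        ids = list(reversed(self._ancestors[tax_id])) + [tax_id]
        return [self._taxa[i] for i in ids]

    def taxa_by_name_token(self, token: str) -> list[int]:
        return sorted(self._name_index.get(token.lower(), ()))

    # -- indexes ------------------------------------------------------------

    def _load_index(self) -> None:
        self._taxon_index: dict[int, set[str]] = {}
        g = self._h5.get("index")
        if g is not None and "taxon" in g:
            for t, a in zip(g["taxon"][:], g["accession"][:]):
                self._taxon_index.setdefault(int(t), set()).add(a.decode())
        self._name_index: dict[str, set[int]] = {}
        for tid, node in self._taxa.items():
            for token in node.name.lower().split():
                self._name_index.setdefault(token, set()).add(tid)
        self._max_dr = 0
        for acc in self.accessions():
            if acc.startswith("DR"):
                self._max_dr = max(self._max_dr, int(acc[2:9]))

    def _write_index(self) -> None:
        if "index" in self._h5:
            del self._h5["index"]
        g = self._h5.create_group("index")
        taxa, accs = [], []
        for t in sorted(self._taxon_index):
            for a in sorted(self._taxon_index[t]):
                taxa.append(t)
                accs.append(a)
        g.create_dataset("taxon", data=np.array(taxa, dtype=np.int64))
        g.create_dataset("accession", data=np.array(accs, dtype="S16"))

    # -- families -----------------------------------------------------------

    def accessions(self) -> list[str]:
        if "families" not in self._h5:
            return []
        return sorted(self._h5["families"].keys())

    def next_accession(self) -> str:
        self._max_dr += 1
        return f"DR{self._max_dr:07d}.1"

    def add_family(self, fam: Family) -> str:
        """Persist a family and update the taxon index.

        With an empty accession, the next free DR number (version .1) is
        auto-assigned.  Duplicate accessions and clade taxa missing from the
        embedded taxonomy are rejected.
        """
        if not fam.accession:
            fam.accession = self.next_accession()
        grp = self._h5.require_group("families")
        if fam.accession in grp:
            raise ParameterError(f"duplicate accession {fam.accession}")
        for tid in fam.clade_taxa:
            if tid not in self._taxa:
                raise LookupFailure(f"clade taxon {tid} absent from taxonomy")
        g = grp.create_group(fam.accession)
        g.attrs["name"] = fam.name
        g.attrs["classification"] = fam.classification
        g.attrs["curated"] = fam.curated
        g.create_dataset("consensus", data=np.bytes_(fam.consensus.encode()))
        g.create_dataset("clade_taxa", data=np.array(fam.clade_taxa, dtype=np.int64))
        g.create_dataset("metadata", data=np.bytes_(json.dumps(fam.metadata).encode()))
        if fam.hmm is not None:
            g.create_dataset("hmm", data=np.bytes_(_hmm_to_json(fam.hmm).encode()))
        if fam.accession.startswith("DR"):
            self._max_dr = max(self._max_dr, int(fam.accession[2:9]))
        for tid in fam.clade_taxa:
            self._taxon_index.setdefault(tid, set()).add(fam.accession)
        return fam.accession

    def get_family(self, accession: str) -> Family:
        try:
            g = self._h5["families"][accession]
        except KeyError:
            raise LookupFailure(f"unknown accession {accession}") from None
        hmm = None
        if "hmm" in g:
            hmm = _hmm_from_json(g["hmm"][()].decode())
        return Family(
            accession=accession,
            name=g.attrs["name"],
            consensus=g["consensus"][()].decode(),
            classification=g.attrs["classification"],
            clade_taxa=[int(t) for t in g["clade_taxa"][:]],
            curated=bool(g.attrs["curated"]),
            hmm=hmm,
            metadata=json.loads(g["metadata"][()].decode()),
        )

    def _descendants(self, tax_id: int) -> Iterable[int]:
        stack = [tax_id]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(self._children.get(node, ()))

    def families_for_taxon(
        self,
        tax_id: int,
        include_ancestors: bool = False,
        include_descendants: bool = False,
    ) -> list[Family]:
        """Families indexed on a taxon, optionally unioned with its root-path
        ancestors and/or subtree.  Deterministic accession order, no
        duplicates."""
        self.taxon(tax_id)
        targets = {tax_id}
        if include_ancestors:
            targets.update(self._ancestors[tax_id])
        if include_descendants:
            targets.update(self._descendants(tax_id))
        accs: set[str] = set()
        for t in targets:
            accs.update(self._taxon_index.get(t, ()))
        return [self.get_family(a) for a in sorted(accs)]

    # -- export -------------------------------------------------------------

    def export(self, selection: list[Family], format: str, path) -> Path:
        """Export a selection as FASTA, EMBL flat entries, or concatenated
        HMM text.  Families without an HMM are skipped (with a warning) in
        hmm format."""
        if not selection:
            raise ParameterError("empty selection")
        path = Path(path)
        if format == "fasta":
            from Bio import SeqIO
            from Bio.Seq import Seq
            from Bio.SeqRecord import SeqRecord

            records = [
                SeqRecord(Seq(f.consensus), id=f.accession, description=f.name)
                for f in selection
            ]
            with open(path, "w") as fh:
                SeqIO.write(records, fh, "fasta")
        elif format == "embl":
            from Bio import SeqIO
            from Bio.Seq import Seq
            from Bio.SeqRecord import SeqRecord

            records = []
            for f in selection:
                rec = SeqRecord(Seq(f.consensus), id=f.accession, name=f.name,
                                description=f.name)
                rec.annotations["molecule_type"] = "DNA"
                rec.annotations["topology"] = "linear"
                rec.annotations["data_file_division"] = "UNC"
                if f.clade_taxa:
                    rec.annotations["taxonomy"] = [
                        n.name for n in self.lineage(f.clade_taxa[0])
                    ]
                    rec.annotations["organism"] = self.taxon(f.clade_taxa[0]).name
                records.append(rec)
            with open(path, "w") as fh:
                SeqIO.write(records, fh, "embl")
        elif format == "hmm":
            import logging
            import tempfile

            from .hmm import write_hmm

            chunks = []
            for f in selection:
                if f.hmm is None:
                    logging.getLogger(__name__).warning(
                        "family %s has no HMM; skipped in hmm export", f.accession
                    )
                    continue
                with tempfile.NamedTemporaryFile("r", suffix=".hmm") as tmp:
                    write_hmm(f.hmm, tmp.name)
                    chunks.append(Path(tmp.name).read_text())
            path.write_text("".join(chunks))
        else:
            raise ParameterError(f"unknown export format {format!r}")
        return path


def create_store(path, taxonomy: list[TaxonNode]) -> FamilyStore:
    """Create a new store with an embedded (validated, immutable) taxonomy."""
    root_id = _validate_taxonomy(taxonomy)
    h5 = h5py.File(path, "w")
    h5.attrs["layout_version"] = LAYOUT_VERSION
    h5.attrs["taxonomy_root"] = root_id
    g = h5.create_group("taxonomy")
    g.create_dataset("tax_id", data=np.array([t.tax_id for t in taxonomy], dtype=np.int64))
    g.create_dataset("parent_id", data=np.array([t.parent_id for t in taxonomy], dtype=np.int64))
    g.create_dataset("name", data=np.array([t.name.encode() for t in taxonomy], dtype="S128"))
    g.create_dataset("rank", data=np.array([t.rank.encode() for t in taxonomy], dtype="S32"))
    h5.create_group("families")
    db = FamilyStore(h5, "w")
    db.flush()
    return db


def open_store(path, mode: str = "r") -> FamilyStore:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    h5 = h5py.File(p, mode)
    if h5.attrs.get("layout_version") != LAYOUT_VERSION:
        h5.close()
        raise FormatError(f"{p}: not a tefamkit family store")
    return FamilyStore(h5, mode)
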
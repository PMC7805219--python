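import numpy as np
import pytest

from tefamkit.errors import FormatError, LookupFailure, ParameterError
from tefamkit.famdb import (
    ACCESSION_RE,
    FamilyStore,
    Family,
    TaxonNode,
    create_store,
    open_store,
)
from tefamkit.hmm import hmm_from_consensus


def toy_taxonomy():
    return [
        TaxonNode(1, 1, "root", "no rank"),
        TaxonNode(2, 1, "Metazoa", "kingdom"),
        TaxonNode(3, 2, "Mammalia", "class"),
        TaxonNode(4, 3, "Homo sapiens", "species"),
        TaxonNode(5, 2, "Aves", "class"),
    ]


def make_family(acc, taxa, with_hmm=False, consensus="ACGTACGTAC"):
    return Family(
        accession=acc,
        name=f"fam-{acc}",
        consensus=consensus,
        clade_taxa=taxa,
        curated=acc.startswith("DF"),
        hmm=hmm_from_consensus(consensus) if with_hmm else None,
        metadata={"description": "test family"},
    )


@pytest.fixture()
def store(tmp_path):
    db = create_store(tmp_path / "t.h5", toy_taxonomy())
    yield db
    db.close()


class TestCreate:
    def test_layout_version_attribute_present(self, tmp_path):
        p = tmp_path / "v.h5"
        create_store(p, toy_taxonomy()).close()
        import h5py

        with h5py.File(p) as h5:
            assert "layout_version" in h5.attrs

    def test_cyclic_taxonomy_rejected(self, tmp_path):
        cyc = [TaxonNode(1, 1, "root"), TaxonNode(2, 3, "a"), TaxonNode(3, 2, "b")]
        with pytest.raises(ParameterError):
            create_store(tmp_path / "c.h5", cyc)

    def test_multiple_roots_rejected(self, tmp_path):
        two = [TaxonNode(1, 1, "r1"), TaxonNode(2, 2, "r2")]
        with pytest.raises(ParameterError):
            create_store(tmp_path / "m.h5", two)

    def test_non_store_file_rejected(self, tmp_path):
        import h5py

        p = tmp_path / "other.h5"
        with h5py.File(p, "w") as h5:
            h5.attrs["something"] = 1
        with pytest.raises(FormatError):
            open_store(p)


def test_full_scale_taxonomy_builds_quickly(tmp_path, rng):
    """A store embedding a 61,003-node synthetic taxonomy (the size of a
    realistic vertebrate-heavy NCBI slice) builds in under a minute."""
    import time

    n = 61_003
    parents = [1] + [int(rng.integers(1, t)) for t in range(2, n + 1)]
    taxonomy = [TaxonNode(t, parents[t - 1], f"taxon{t}") for t in range(1, n + 1)]
    t0 = time.time()
    db = create_store(tmp_path / "big.h5", taxonomy)
    db.close()
    assert time.time() - t0 < 60
    with open_store(tmp_path / "big.h5") as db:
        assert len(db.lineage(n)) >= 2


class TestAccessions:
    @pytest.mark.parametrize("acc,ok", [
        ("DR0086957.1", True),
        ("DF0000001.4", True),
        ("DR000001.1", False),      # 6 digits
        ("DX0000001.1", False),     # bad prefix
        ("DR0000001", False),       # no version
    ])
    def test_grammar(self, acc, ok):
        assert bool(ACCESSION_RE.match(acc)) == ok

    def test_prefix_must_match_curated_flag(self):
        with pytest.raises(ParameterError):
            Family(accession="DF0000001.1", name="x", consensus="ACGT",
                   curated=False)

    def test_auto_assignment_strictly_increases(self, store):
        accs = []
        for _ in range(5):
            f = make_family(store.next_accession(), [2])
            accs.append(store.add_family(f))
        numbers = [int(a[2:9]) for a in accs]
        assert numbers == sorted(numbers)
        assert len(set(numbers)) == 5

    def test_duplicate_accession_rejected(self, store):
        store.add_family(make_family("DR0000001.1", [2]))
        with pytest.raises(ParameterError):
            store.add_family(make_family("DR0000001.1", [3]))

    def test_unknown_clade_taxon_rejected(self, store):
        with pytest.raises(LookupFailure):
            store.add_family(make_family("DR0000001.1", [99]))


class TestRoundTrip:
    def test_all_fields_survive_reopen(self, tmp_path):
        p = tmp_path / "rt.h5"
        db = create_store(p, toy_taxonomy())
        fam = make_family("DR0000001.1", [3, 5], with_hmm=True,
                          consensus="ACGTACGTACGTACGT")
        db.add_family(fam)
        db.close()
        db = open_store(p)
        back = db.get_family("DR0000001.1")
        assert back.consensus == fam.consensus
        assert back.name == fam.name
        assert back.clade_taxa == [3, 5]
        assert back.curated is False
        assert back.metadata == fam.metadata
        assert np.allclose(back.hmm.match_emissions, fam.hmm.match_emissions,
                           atol=1e-12)
        assert np.allclose(back.hmm.t_mm, fam.hmm.t_mm, atol=1e-12)
        assert back.hmm.consensus_map == fam.hmm.consensus_map
        db.close()


class TestQueries:
    def test_node_ancestor_descendant_semantics(self, store):
        store.add_family(make_family("DR0000010.1", [3]))  # on Mammalia
        direct = [f.accession for f in store.families_for_taxon(3)]
        assert direct == ["DR0000010.1"]
        child = [f.accession
                 for f in store.families_for_taxon(4, include_ancestors=True)]
        assert child == ["DR0000010.1"]
        assert store.families_for_taxon(4) == []
        assert store.families_for_taxon(5, include_ancestors=True) == []
        up = [f.accession
              for f in store.families_for_taxon(2, include_descendants=True)]
        assert up == ["DR0000010.1"]

    def test_unknown_taxon_rejected(self, store):
        with pytest.raises(LookupFailure):
            store.families_for_taxon(12345)

    def test_query_equals_brute_force_scan(self, tmp_path, rng):
        """Indexed queries equal a linear scan over every family, including
        ancestor/descendant expansion, on a randomized store."""
        taxonomy = [TaxonNode(1, 1, "root")]
        for t in range(2, 80):
            taxonomy.append(TaxonNode(t, int(rng.integers(1, t)), f"taxon{t}"))
        db = create_store(tmp_path / "q.h5", taxonomy)
        families = []
        for i in range(1, 201):
            taxa = sorted(set(map(int, rng.integers(1, 80, size=rng.integers(1, 4)))))
            fam = make_family(f"DR{i:07d}.1", taxa)
            db.add_family(fam)
            families.append(fam)

        parent = {t.tax_id: t.parent_id for t in taxonomy}

        def ancestors(t):
            out = set()
            while t != 1:
                t = parent[t]
                out.add(t)
            return out

        def descendants(t):
            return {x.tax_id for x in taxonomy
                    if t in ancestors(x.tax_id) or x.tax_id == t}

        for _ in range(100):
            q = int(rng.integers(1, 80))
            inc_a = bool(rng.integers(2))
            inc_d = bool(rng.integers(2))
            targets = {q}
            if inc_a:
                targets |= ancestors(q)
            if inc_d:
                targets |= descendants(q)
            expected = sorted(f.accession for f in families
                              if targets & set(f.clade_taxa))
            got = [f.accession for f in db.families_for_taxon(
                q, include_ancestors=inc_a, include_descendants=inc_d)]
            assert got == expected
        db.close()

    def test_lineage_is_root_to_taxon(self, store):
        names = [n.name for n in store.lineage(4)]
        assert names == ["root", "Metazoa", "Mammalia", "Homo sapiens"]

    def test_name_token_lookup(self, store):
        assert store.taxa_by_name_token("homo") == [4]
        assert store.taxa_by_name_token("sapiens") == [4]


class TestExport:
    def test_fasta_round_trip(self, store, tmp_path):
        from Bio import SeqIO

        store.add_family(make_family("DR0000001.1", [4], consensus="ACGT" * 12))
        fams = store.families_for_taxon(4)
        out = store.export(fams, "fasta", tmp_path / "x.fa")
        recs = list(SeqIO.parse(str(out), "fasta"))
        assert len(recs) == 1
        assert recs[0].id == "DR0000001.1"
        assert str(recs[0].seq) == "ACGT" * 12

    def test_embl_round_trip_preserves_sequence(self, store, tmp_path):
        from Bio import SeqIO

        store.add_family(make_family("DR0000002.1", [4], consensus="ACGTTGCA" * 8))
        fams = store.families_for_taxon(4)
        out = store.export(fams, "embl", tmp_path / "x.embl")
        recs = list(SeqIO.parse(str(out), "embl"))
        assert str(recs[0].seq) == "ACGTTGCA" * 8
        text = out.read_text()
        assert text.startswith("ID")
        assert "OC" in text  # lineage line from the embedded taxonomy

    def test_hmm_export_skips_families_without_model(self, store, tmp_path):
        store.add_family(make_family("DR0000003.1", [4], with_hmm=True))
        store.add_family(make_family("DR0000004.1", [4], with_hmm=False))
        fams = store.families_for_taxon(4)
        out = store.export(fams, "hmm", tmp_path / "x.hmm")
        assert out.read_text().count("HMMER3") == 1

    def test_export_matches_selection(self, store, tmp_path):
        from Bio import SeqIO

        store.add_family(make_family("DR0000005.1", [3]))
        store.add_family(make_family("DR0000006.1", [5]))
        fams = store.families_for_taxon(4, include_ancestors=True)
        out = store.export(fams, "fasta", tmp_path / "clade.fa")
        ids = [r.id for r in SeqIO.parse(str(out), "fasta")]
        assert ids == [f.accession for f in fams] == ["DR0000005.1"]

    def test_empty_selection_rejected(self, store, tmp_path):
        with pytest.raises(ParameterError):
            store.export([], "fasta", tmp_path / "e.fa")

    def test_unknown_format_rejected(self, store, tmp_path):
        store.add_family(make_family("DR0000007.1", [4]))
        with pytest.raises(ParameterError):
            store.export(store.families_for_taxon(4), "genbank", tmp_path / "g")
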
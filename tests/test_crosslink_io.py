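import collections

import pytest
from hypothesis import given, settings, strategies as st

from xlmap.crosslink_io import (CrossLink, LinkerSpec, group_ppis,
                                load_linker_table, make_link, parse_fasta,
                                parse_generic, parse_plink2, write_generic,
                                write_linker_table, DEFAULT_LINKERS)
from xlmap.errors import EmptyInputError, InputFormatError


@pytest.fixture
def sequences(tmp_path):
    fasta = tmp_path / "db.fasta"
    fasta.write_text(
        ">P1 test protein one\n" + "MKVLAEGHIRWQSTNDYCFP" * 5 + "\n"
        ">sp|P02769|ALBU_BOVIN\nMKWVTFISLLLLFSSAYS\n"
        ">P3\nACDEFGHIKLMNPQRSTVWY\n")
    return parse_fasta(fasta)


class TestParseFasta:
    def test_single_record_identity(self, tmp_path):
        f = tmp_path / "one.fasta"
        f.write_text(">P1\nMKV\n")
        recs = parse_fasta(f)
        assert set(recs) == {"P1"}
        assert recs["P1"].sequence == "MKV"
        assert len(recs["P1"]) == 3

    def test_uniprot_header_resolves_to_accession(self, sequences):
        assert "P02769" in sequences

    def test_duplicate_accession_keeps_first(self, tmp_path, caplog):
        f = tmp_path / "dup.fasta"
        f.write_text(">P1\nMKV\n>P1\nAAAA\n")
        with caplog.at_level("WARNING", logger="xlmap"):
            recs = parse_fasta(f)
        assert recs["P1"].sequence == "MKV"
        assert any("duplicate" in r.message for r in caplog.records)

    def test_empty_file_raises(self, tmp_path):
        f = tmp_path / "empty.fasta"
        f.write_text("")
        with pytest.raises(EmptyInputError):
            parse_fasta(f)

    def test_nonstandard_letters_fold_to_x_and_gaps_strip(self, tmp_path):
        f = tmp_path / "odd.fasta"
        f.write_text(">P1\nmk-v*UZB\n")
        assert parse_fasta(f)["P1"].sequence == "MKVXXX"


def _plink_csv(tmp_path, rows, linker_col=False):
    path = tmp_path / "plink.csv"
    header = "Order,Proteins" + (",Linker" if linker_col else "")
    lines = [header] + [",".join(map(str, (i + 1,) + tuple(r)))
                        for i, r in enumerate(rows)]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestParsePlink2:
    def test_canonical_ordering_dedups_psms(self, tmp_path, sequences):
        path = _plink_csv(tmp_path, [("P1(5)-P02769(9)",),
                                     ("P1(5)-P02769(9)",),
                                     ("P02769(9)-P1(5)",)])
        links, rejections = parse_plink2(path, sequences)
        assert len(links) == 1 and not rejections
        assert links[0].spectral_count == 3
        assert (links[0].protein_a, links[0].pos_a) == ("P02769", 9)

    def test_out_of_bounds_site_rejected(self, tmp_path, sequences):
        path = _plink_csv(tmp_path, [("P1(999)-P3(3)",)])
        links, rejections = parse_plink2(path, sequences)
        assert links == [] and len(rejections) == 1
        assert "exceeds length" in rejections[0].reason

    def test_unknown_accession_rejected(self, tmp_path, sequences):
        path = _plink_csv(tmp_path, [("NOPE(5)-P3(3)",)])
        _, rejections = parse_plink2(path, sequences)
        assert "not in FASTA" in rejections[0].reason

    def test_malformed_and_ambiguous_rows_skipped(self, tmp_path, sequences):
        path = _plink_csv(tmp_path, [("garbage",),
                                     ("P1(5)-P3(3)/P1(6)-P3(3)/",)])
        links, rejections = parse_plink2(path, sequences)
        assert links == [] and len(rejections) == 2

    def test_uniprot_piped_site_strings(self, tmp_path, sequences):
        path = _plink_csv(tmp_path, [("sp|P02769|ALBU_BOVIN(4)-P3(7)/",)])
        links, _ = parse_plink2(path, sequences)
        assert links[0].protein_a == "P02769"

    def test_linker_column_used_when_present(self, tmp_path, sequences):
        path = _plink_csv(tmp_path, [("P1(5)-P3(3)", "DSBU")], linker_col=True)
        links, _ = parse_plink2(path, sequences)
        assert links[0].linker == "DSBU"

    def test_groupby_oracle_on_generated_rows(self, tmp_path, sequences):
        # 10 PSM rows over 4 distinct site pairs; expected collapse computed
        # with an independent Counter-based group-by
        pairs = ["P1(5)-P3(9)", "P1(7)-P3(9)", "P3(2)-P1(5)", "P1(1)-P1(8)"]
        rows = [pairs[i % 4] for i in range(8)] + [pairs[0], pairs[0]]
        expected = collections.Counter()
        for r in rows:
            a, b = r.split("-")
            sites = sorted(((a[:a.index("(")], int(a[a.index("(") + 1:-1])),
                            (b[:b.index("(")], int(b[b.index("(") + 1:-1]))))
            expected[(sites[0][0], sites[0][1], sites[1][0], sites[1][1])] += 1
        links, rejections = parse_plink2(_plink_csv(tmp_path, [(r,) for r in rows]),
                                         sequences)
        assert not rejections
        assert len(links) == 4
        assert sum(l.spectral_count for l in links) == 10
        got = {(l.protein_a, l.pos_a, l.protein_b, l.pos_b): l.spectral_count
               for l in links}
        assert got == dict(expected)


def _generic_tsv(tmp_path, rows, header="protein_a\tpos_a\tprotein_b\tpos_b\tlinker\tcount"):
    path = tmp_path / "links.tsv"
    path.write_text("\n".join([header] + ["\t".join(map(str, r)) for r in rows]) + "\n")
    return path


class TestParseGeneric:
    def test_single_row(self, tmp_path, sequences):
        path = _generic_tsv(tmp_path, [("P1", 5, "P3", 9, "DSS", 1)])
        links, rejections = parse_generic(path, sequences)
        assert len(links) == 1 and links[0].spectral_count == 1

    def test_non_integer_position_skipped(self, tmp_path, sequences):
        path = _generic_tsv(tmp_path, [("P1", "abc", "P3", 9, "DSS", 1)])
        links, rejections = parse_generic(path, sequences)
        assert links == [] and len(rejections) == 1

    def test_linker_is_part_of_dedup_key(self, tmp_path, sequences):
        path = _generic_tsv(tmp_path, [("P1", 5, "P3", 9, "DSS", 1),
                                       ("P1", 5, "P3", 9, "DSBU", 1)])
        links, _ = parse_generic(path, sequences)
        assert len(links) == 2

    def test_missing_mandatory_column_is_fatal(self, tmp_path, sequences):
        path = _generic_tsv(tmp_path, [("P1", 5, "P3", 9)],
                            header="protein_a\tpos_a\tprotein_b\tpos_b")
        with pytest.raises(InputFormatError, match="linker"):
            parse_generic(path, sequences)

    def test_count_column_conservation(self, tmp_path, sequences):
        rows = [("P1", 5, "P3", 9, "DSS", 3), ("P3", 9, "P1", 5, "DSS", 2),
                ("P1", 7, "P3", 1, "DSS", 4)]
        links, _ = parse_generic(_generic_tsv(tmp_path, rows), sequences)
        assert sum(l.spectral_count for l in links) == 9
        assert len(links) == 2

    def test_roundtrip_through_generic_tsv(self, tmp_path, sequences):
        rows = [("P1", 5, "P3", 9, "DSS", 3), ("P1", 1, "P1", 8, "BS3", 2)]
        links, _ = parse_generic(_generic_tsv(tmp_path, rows), sequences)
        out = tmp_path / "rt.tsv"
        write_generic(links, out)
        links2, rejections = parse_generic(out, sequences)
        assert links2 == links and not rejections


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(
    st.tuples(st.sampled_from(["P1", "P3"]), st.integers(1, 20),
              st.sampled_from(["P1", "P3"]), st.integers(1, 20),
              st.sampled_from(["DSS", "BS3"])),
    min_size=1, max_size=15),
    st.randoms(use_true_random=False))
def test_dedup_key_invariant_under_row_permutation(tmp_path_factory, rows, rnd):
    """The dedup key is exactly (sites + linker), whatever the row order."""
    tmp_path = tmp_path_factory.mktemp("hyp")
    fasta = tmp_path / "db.fasta"
    fasta.write_text(">P1\n" + "A" * 20 + "\n>P3\n" + "C" * 20 + "\n")
    seqs = parse_fasta(fasta)
    shuffled = list(rows)
    rnd.shuffle(shuffled)
    base = [(pa, a, pb, b, lk, 1) for pa, a, pb, b, lk in rows]
    perm = [(pa, a, pb, b, lk, 1) for pa, a, pb, b, lk in shuffled]
    links1, _ = parse_generic(_generic_tsv(tmp_path, base), seqs)
    links2, _ = parse_generic(_generic_tsv(tmp_path, perm), seqs)
    assert links1 == links2
    expected = collections.Counter(
        tuple(sorted([(pa, a), (pb, b)])) + (lk,) for pa, a, pb, b, lk in rows)
    assert len(links1) == len(expected)


class TestGroupPpis:
    def test_partition_by_protein_pair(self):
        links = [make_link("P1", 1, "P2", 5, "DSS"),
                 make_link("P1", 3, "P2", 9, "DSS"),
                 make_link("P1", 2, "P3", 4, "DSS")]
        ppis = group_ppis(links)
        assert [p.key for p in ppis] == [("P1", "P2"), ("P1", "P3")]
        assert [len(p.links) for p in ppis] == [2, 1]
        assert sum(len(p.links) for p in ppis) == 3

    def test_intra_protein_ppi_flagged(self):
        ppis = group_ppis([make_link("P1", 2, "P1", 9, "DSS")])
        assert len(ppis) == 1 and ppis[0].is_intra

    def test_empty_input(self):
        assert group_ppis([]) == []


class TestLinkerTable:
    def test_roundtrip_and_defaults(self, tmp_path):
        path = tmp_path / "linkers.tsv"
        write_linker_table(DEFAULT_LINKERS, path)
        table = load_linker_table(path)
        assert table == DEFAULT_LINKERS
        assert table["DSS"].max_ca_distance == 30.0

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            LinkerSpec("BAD", 0.0)
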
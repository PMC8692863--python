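"""Support counting, isoform status calls, ambiguity flags, report dialect."""

import pytest

from splicequery.local_align import AlignmentResult
from splicequery.support_caller import (
    SupportMatrix,
    build_support_matrix,
    call_isoforms,
    count_junction_support,
    format_cell,
    render_transcript_table,
    write_report,
)


def make_result(query_id, read_id, significant=True):
    return AlignmentResult(
        query_id=query_id, read_id=read_id, query_span=(1, 50), read_span=(1, 50),
        read_orientation="forward", matches=50, alignment_columns=50, score=100.0,
        identity_pct=100.0 if significant else 90.0,
        query_cover_pct=100.0, significant=significant,
    )


@pytest.fixture
def identity_strs(catalog):
    return [j.identity_str for j in catalog.junctions]


class TestCounting:
    def test_mixed_significance_counts_only_significant(self, catalog, identity_strs):
        q = identity_strs[0]
        alns = [make_result(q, f"r{i}") for i in range(3)] + [
            make_result(q, f"n{i}", significant=False) for i in range(2)
        ]
        row = count_junction_support(alns, catalog, "s")
        ident = catalog.identities[0]
        assert row[ident] == 3
        assert sum(row.values()) == 3

    def test_duplicate_read_ids_vote_once(self, catalog, identity_strs):
        q = identity_strs[0]
        alns = [make_result(q, "same_read"), make_result(q, "same_read")]
        row = count_junction_support(alns, catalog, "s")
        assert row[catalog.identities[0]] == 1

    def test_no_alignments_gives_explicit_zeros(self, catalog):
        row = count_junction_support([], catalog, "s")
        assert set(row.values()) == {0}
        assert len(row) == len(catalog)

    def test_unknown_junction_is_an_error(self, catalog):
        with pytest.raises(KeyError, match="absent from the catalog"):
            count_junction_support([make_result("chrX:+:1:2", "r")], catalog, "s")

    def test_conservation_of_significant_pairs(self, catalog, identity_strs):
        alns = [
            make_result(identity_strs[i % 3], f"r{i}", significant=(i % 2 == 0))
            for i in range(20)
        ]
        m = build_support_matrix({"s": alns}, catalog)
        expected = len({(a.read_id, a.query_id) for a in alns if a.significant})
        assert m.total() == expected


class TestCalls:
    def test_empty_matrix_gives_all_none(self, catalog, models):
        m = SupportMatrix(samples=["s"], catalog=catalog)
        calls = call_isoforms(m, models)
        assert {c.status for c in calls} == {"none"}

    def test_full_requires_every_junction(self, catalog, models, identity_strs):
        # support all three DSCR4-202 junctions -> full, even though E1-E2 is shared
        d202 = {j.identity for j in catalog.transcript_junctions("DSCR4-202")}
        alns = [
            make_result(f"{c}:{s}:{d}:{a}", f"r{i}")
            for i, (c, s, d, a) in enumerate(d202)
        ]
        m = build_support_matrix({"testis": alns}, catalog)
        call = {c.transcript_id: c for c in call_isoforms(m, models)}
        assert call["DSCR4-202"].status == "full"
        assert call["DSCR4-202"].uniquely_confirmed
        # DSCR4-203 sees only the shared first junction -> partial, not unique
        assert call["DSCR4-203"].status == "partial"
        assert not call["DSCR4-203"].uniquely_confirmed
        assert call["KCNJ6-201"].status == "none"

    def test_shared_only_support_is_partial_and_not_unique(self, catalog, models):
        (shared4,) = [j for j in catalog.junctions if len(j.transcript_ids) == 4]
        alns = [make_result(shared4.identity_str, f"r{i}") for i in range(17)]
        m = build_support_matrix({"placenta": alns}, catalog)
        call = {c.transcript_id: c for c in call_isoforms(m, models)}
        for tid in ("DSCR4-201", "DSCR4-202", "DSCR4-203", "KCNJ6-202"):
            assert call[tid].status == "partial"
            assert not call[tid].uniquely_confirmed

    def test_every_multi_member_junction_is_flagged_ambiguous(self, catalog, models):
        m = SupportMatrix(samples=["s"], catalog=catalog)
        calls = call_isoforms(m, models)
        k202 = next(c for c in calls if c.transcript_id == "KCNJ6-202")
        assert set(k202.ambiguous_junctions) == {"E1b-E1bis", "E2-E3", "E3-E4b"}
        d201 = next(c for c in calls if c.transcript_id == "DSCR4-201")
        assert set(d201.ambiguous_junctions) == {"E1-E2"}

    def test_adding_reads_never_demotes_status(self, catalog, models, identity_strs):
        rank = {"none": 0, "partial": 1, "full": 2}
        alns = [make_result(identity_strs[i], f"r{i}") for i in range(len(identity_strs))]
        prev = None
        for n in range(len(alns) + 1):
            m = build_support_matrix({"s": alns[:n]}, catalog)
            calls = {c.transcript_id: c for c in call_isoforms(m, models)}
            if prev is not None:
                for tid, c in calls.items():
                    assert rank[c.status] >= rank[prev[tid].status]
            prev = calls


class TestReportDialect:
    @pytest.mark.parametrize(
        "count,shared,expected",
        [
            (0, False, "No"),
            (0, True, "No"),
            (1, False, "1 alignment"),
            (1, True, "1 alignment*"),
            (33, True, "33 alignments*"),
            (10, False, "10 alignments"),
        ],
    )
    def test_cell_formatting(self, count, shared, expected):
        assert format_cell(count, shared) == expected

    def test_testis_row_matches_published_shape(self, catalog, models):
        # counts (33 shared, 1, 1) on DSCR4-202's junctions render exactly as
        # "33 alignments*", "1 alignment", "1 alignment"
        jxs = catalog.transcript_junctions("DSCR4-202")
        m = SupportMatrix(samples=["Testis"], catalog=catalog)
        m.add_sample("Testis", {jxs[0].identity: 33, jxs[1].identity: 1, jxs[2].identity: 1})
        table = render_transcript_table(m, "DSCR4-202")
        assert list(table.columns) == ["E1-E2", "E2-E3", "E3-E4"]
        assert list(table.loc["Testis"]) == ["33 alignments*", "1 alignment", "1 alignment"]

    def test_all_zero_row_renders_no_everywhere(self, catalog):
        m = SupportMatrix(samples=["Liver"], catalog=catalog)
        table = render_transcript_table(m, "DSCR4-203")
        assert set(table.loc["Liver"]) == {"No"}
        assert list(table.columns) == ["E1-E2", "E2-E3", "E3-E4", "E4-E5", "E5-E6"]

    def test_write_report_is_byte_deterministic(self, catalog, models, tmp_path, identity_strs):
        alns = [make_result(identity_strs[i % 4], f"r{i}") for i in range(12)]
        m = build_support_matrix({"s": alns}, catalog)
        calls = call_isoforms(m, models)
        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        w1 = write_report(calls, m, d1)
        w2 = write_report(calls, m, d2)
        assert set(w1) == set(w2)
        for k in w1:
            assert w1[k].read_bytes() == w2[k].read_bytes()
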
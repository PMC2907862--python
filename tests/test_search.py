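import numpy as np
import pytest
from click.testing import CliRunner

from swsearch import (
    DatabaseRecord,
    compute_gcups,
    mutate_homolog,
    read_fasta,
    search,
)
from swsearch.search import InputFormatError, main

from .conftest import random_protein_str


@pytest.fixture
def small_db(rng):
    base = random_protein_str(rng, 80)
    shuffled = "".join(rng.permutation(list(base)))
    records = [
        DatabaseRecord(id="self", description="exact copy", sequence=base),
        DatabaseRecord(id="shuffled", description="", sequence=shuffled),
        DatabaseRecord(
            id="random", description="", sequence=random_protein_str(rng, 80)
        ),
        DatabaseRecord(
            id="homolog",
            description="",
            sequence=mutate_homolog(base, 0.1, 0.02, seed=7),
        ),
    ]
    return DatabaseRecord(id="query", description="", sequence=base), records


class TestReadFasta:
    def test_two_records_with_lengths(self, tmp_path):
        p = tmp_path / "db.fasta"
        p.write_text(">a first\nACDE\nFGH\n\n>b second\nWYV\n")
        recs = read_fasta(p)
        assert [(r.id, r.length) for r in recs] == [("a", 7), ("b", 3)]
        assert recs[0].sequence == "ACDEFGH"  # multi-line concatenation
        assert recs[0].description == "first"

    def test_star_only_record_dropped(self, tmp_path, caplog):
        p = tmp_path / "db.fasta"
        p.write_text(">empty\n***\n>ok\nACD\n")
        with caplog.at_level("WARNING"):
            recs = read_fasta(p)
        assert [r.id for r in recs] == ["ok"]
        assert "empty" in caplog.text

    def test_missing_and_empty_files(self, tmp_path):
        with pytest.raises(InputFormatError):
            read_fasta(tmp_path / "nope.fasta")
        p = tmp_path / "blank.fasta"
        p.write_text("")
        with pytest.raises(InputFormatError):
            read_fasta(p)


class TestSearch:
    def test_exact_copy_ranks_first(self, scheme62, small_db):
        query, db = small_db
        result = search(query, db, scheme62, engine="scalar")
        assert result.hits[0].subject_id == "self"
        scores = [h.score for h in result.hits]
        assert scores == sorted(scores, reverse=True)

    def test_homolog_outranks_random(self, scheme62, small_db):
        query, db = small_db
        result = search(query, db, scheme62, engine="scalar")
        ranks = {h.subject_id: h.rank for h in result.hits}
        assert ranks["homolog"] < ranks["random"]

    def test_engines_agree_on_ranking(self, scheme62, small_db, rng):
        query, db = small_db
        db = db + [
            DatabaseRecord(id=f"extra{i}", description="", sequence=random_protein_str(rng, int(rng.integers(20, 120))))
            for i in range(10)
        ]
        results = {
            eng: search(query, db, scheme62, engine=eng, VL=8, PL=32, topk=100)
            for eng in ("scalar", "striped", "partitioned")
        }
        ref = [(h.subject_id, h.score) for h in results["scalar"].hits]
        for eng in ("striped", "partitioned"):
            assert [(h.subject_id, h.score) for h in results[eng].hits] == ref

    def test_topk_clamps_to_database_size(self, scheme62, small_db):
        query, db = small_db
        result = search(query, db, scheme62, topk=999)
        assert len(result.hits) == len(db)

    def test_cell_count(self, scheme62, small_db):
        query, db = small_db
        result = search(query, db, scheme62)
        assert result.cell_count == len(query.sequence) * sum(
            r.length for r in db
        )

    def test_tie_break_by_input_order(self, scheme62):
        q = DatabaseRecord(id="q", description="", sequence="ACDEFGHIKL")
        twin = DatabaseRecord(id="twin_a", description="", sequence="ACDEFGHIKL")
        twin2 = DatabaseRecord(id="twin_b", description="", sequence="ACDEFGHIKL")
        result = search(q, [twin, twin2], scheme62)
        assert [h.subject_id for h in result.hits] == ["twin_a", "twin_b"]

    def test_unknown_engine_rejected(self, scheme62, small_db):
        query, db = small_db
        with pytest.raises(ValueError):
            search(query, db, scheme62, engine="warp")


class TestGcups:
    def test_unit_definition(self):
        assert compute_gcups(10**9, 1.0) == 1.0
        assert compute_gcups(0, 1.0) == 0.0

    def test_proportionality(self):
        assert compute_gcups(10**9, 2.0) == pytest.approx(
            compute_gcups(10**9, 1.0) / 2
        )

    def test_non_positive_elapsed_rejected(self):
        with pytest.raises(ValueError):
            compute_gcups(100, 0.0)


class TestCli:
    @pytest.fixture
    def fasta_pair(self, tmp_path, rng):
        q = tmp_path / "q.fasta"
        base = random_protein_str(rng, 60)
        q.write_text(f">query\n{base}\n")
        db = tmp_path / "db.fasta"
        db.write_text(
            f">hit homologous\n{mutate_homolog(base, 0.05, 0.01, seed=3)}\n"
            f">decoy\n{random_protein_str(rng, 60)}\n"
        )
        return q, db

    def test_search_writes_ranked_tsv(self, tmp_path, fasta_pair):
        q, db = fasta_pair
        out = tmp_path / "res.tsv"
        r = CliRunner().invoke(
            main,
            ["--query", str(q), "--db", str(db), "--engine", "partitioned",
             "--vl", "8", "--pl", "32", "--out", str(out), "--seed-check"],
        )
        assert r.exit_code == 0, r.output
        lines = out.read_text().splitlines()
        meta = [l for l in lines if l.startswith("#")]
        assert any("engine=partitioned" in l for l in meta)
        assert any("gcups=" in l for l in meta)
        body = [l for l in lines if not l.startswith("#")]
        assert body[0] == "rank\tsubject_id\tsubject_length\tscore"
        assert body[1].startswith("1\thit\t")

    def test_usage_error_exit_code(self):
        r = CliRunner().invoke(main, ["--query", "q.fasta"])  # --db missing
        assert r.exit_code == 2

    def test_bad_gap_spec_is_usage_error(self, fasta_pair):
        q, db = fasta_pair
        r = CliRunner().invoke(
            main, ["--query", str(q), "--db", str(db), "--gap", "10-0k"]
        )
        assert r.exit_code == 2

    def test_missing_input_exit_code(self, tmp_path, fasta_pair):
        q, _ = fasta_pair
        r = CliRunner().invoke(
            main, ["--query", str(q), "--db", str(tmp_path / "none.fasta")]
        )
        assert r.exit_code == 3
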
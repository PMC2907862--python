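"""Database search driver and the ``swsearch`` command-line tool.

Reads a FASTA query and database, scores every subject with the chosen
engine (scalar reference, striped, or partitioned), returns a stable ranked
list, and reports throughput in GCUPS (billions of DP cell updates per
second, cells = query length x total subject residues). All engines produce
identical scores and therefore identical rankings; the engine choice only
changes how the scores are computed.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
from Bio import SeqIO

from .partitioned_engine import (
    DEFAULT_PL,
    DEFAULT_VL,
    partition_query,
    partitioned_align,
)
from .profile import build_striped_profile
from .scalar_engine import sw_score
from .scoring import (
    GapPenalty,
    GapSpecError,
    MatrixFormatError,
    ScoringScheme,
    load_matrix,
    parse_gap_spec,
)
from .striped_engine import striped_align

__all__ = [
    "DatabaseRecord",
    "Hit",
    "SearchResult",
    "InputFormatError",
    "read_fasta",
    "search",
    "compute_gcups",
    "ENGINES",
    "main",
]

logger = logging.getLogger(__name__)

ENGINES = ("scalar", "striped", "partitioned")

EXIT_USAGE = 2
EXIT_INPUT = 3


class InputFormatError(ValueError):
    """Raised for unreadable or empty sequence inputs."""


@dataclass(frozen=True)
class DatabaseRecord:
    """One FASTA record: header id, description remainder, cleaned sequence."""

    id: str
    description: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Hit:
    rank: int
    subject_id: str
    subject_length: int
    score: int


@dataclass(frozen=True)
class SearchResult:
    """Ranked hits plus run metadata.

    Scores are non-increasing with rank; ties keep database input order.
    ``cell_count`` is query length x total subject residues; ``gcups`` is
    informational (hardware-dependent) and never asserted by tests.
    """

    hits: tuple[Hit, ...]
    engine: str
    matrix_name: str
    gap: GapPenalty
    VL: int | None
    PL: int | None
    cell_count: int
    elapsed: float
    gcups: float
    scores: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(h.rank, h.subject_id, h.subject_length, h.score) for h in self.hits],
            columns=["rank", "subject_id", "subject_length", "score"],
        )

    def write_tsv(self, stream) -> None:
        stream.write(f"# engine={self.engine}\n")
        stream.write(f"# matrix={self.matrix_name} gap={self.gap}")
        if self.engine != "scalar":
            stream.write(f" VL={self.VL}")
        if self.engine == "partitioned":
            stream.write(f" PL={self.PL}")
        stream.write("\n")
        stream.write(
            f"# cells={self.cell_count} elapsed={self.elapsed:.3f}s "
            f"gcups={self.gcups:.6f}\n"
        )
        stream.write("rank\tsubject_id\tsubject_length\tscore\n")
        for h in self.hits:
            stream.write(
                f"{h.rank}\t{h.subject_id}\t{h.subject_length}\t{h.score}\n"
            )


def _clean(seq: str) -> str:
    return "".join(seq.split()).replace("*", "").upper()


def read_fasta(path: str | Path) -> list[DatabaseRecord]:
    """Read FASTA records; empty records are dropped with a warning."""
    path = Path(path)
    if not path.is_file():
        raise InputFormatError(f"no such FASTA file: {path}")
    records: list[DatabaseRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _clean(str(rec.seq))
        if not seq:
            logger.warning("dropping empty record %r", rec.id)
            continue
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        records.append(DatabaseRecord(id=rec.id, description=desc, sequence=seq))
    if not records:
        raise InputFormatError(f"{path} contains no non-empty FASTA records")
    return records


def compute_gcups(cell_count: int, elapsed: float) -> float:
    """Billions of DP cell updates per second."""
    if elapsed <= 0:
        raise ValueError(f"elapsed time must be positive, got {elapsed}")
    return cell_count / elapsed / 1e9


def _score_database(q, subjects, scheme, engine, VL, PL):
    if engine == "scalar":
        return [sw_score(q, s, scheme) for s in subjects]
    if engine == "striped":
        profile = build_striped_profile(q, scheme.matrix, VL)
        return [striped_align(profile, s, scheme.gap).best for s in subjects]
    if engine == "partitioned":
        plan = partition_query(q, PL, VL, scheme.matrix)
        return [partitioned_align(plan, s, scheme.gap) for s in subjects]
    raise ValueError(f"unknown engine {engine!r}; choose from {ENGINES}")


def search(
    query: DatabaseRecord,
    db: list[DatabaseRecord],
    scheme: ScoringScheme,
    engine: str = "scalar",
    VL: int = DEFAULT_VL,
    PL: int = DEFAULT_PL,
    topk: int = 10,
) -> SearchResult:
    """Score every database subject against the query and rank the results."""
    if engine not in ENGINES:
        raise ValueError(f"unknown engine {engine!r}; choose from {ENGINES}")
    if not db:
        raise InputFormatError("empty database")
    alphabet = scheme.alphabet
    q = alphabet.encode(query.sequence)
    if q.size == 0:
        raise InputFormatError("query is empty after encoding")
    subjects = [alphabet.encode(r.sequence) for r in db]
    if any(s.size == 0 for s in subjects):
        raise InputFormatError("database contains an empty record")

    t0 = time.perf_counter()
    scores = np.asarray(_score_database(q, subjects, scheme, engine, VL, PL))
    elapsed = max(time.perf_counter() - t0, 1e-12)

    cell_count = int(q.size * sum(s.size for s in subjects))
    order = np.argsort(-scores, kind="stable")  # ties keep input order
    topk = min(max(topk, 0), len(db)) or len(db)
    hits = tuple(
        Hit(
            rank=rank + 1,
            subject_id=db[i].id,
            subject_length=len(subjects[i]),
            score=int(scores[i]),
        )
        for rank, i in enumerate(order[:topk])
    )
    return SearchResult(
        hits=hits,
        engine=engine,
        matrix_name=scheme.matrix.name,
        gap=scheme.gap,
        VL=VL if engine != "scalar" else None,
        PL=PL if engine == "partitioned" else None,
        cell_count=cell_count,
        elapsed=elapsed,
        gcups=compute_gcups(cell_count, elapsed),
        scores=scores,
    )


@click.command(name="swsearch")
@click.option("--query", "query_path", required=True, help="Query FASTA file.")
@click.option("--db", "db_path", required=True, help="Database FASTA file.")
@click.option(
    "--matrix",
    default="BLOSUM62",
    show_default=True,
    help="BLOSUM62, BLOSUM50 or a path to an NCBI-format matrix file.",
)
@click.option("--gap", "gap_spec", default=None, help='Gap penalty, e.g. "10-2k".')
@click.option("--gap-open", default=10, show_default=True, type=int)
@click.option("--gap-extend", default=2, show_default=True, type=int)
@click.option(
    "--engine",
    type=click.Choice(ENGINES),
    default="partitioned",
    show_default=True,
)
@click.option("--vl", default=DEFAULT_VL, show_default=True, type=int)
@click.option("--pl", default=DEFAULT_PL, show_default=True, type=int)
@click.option("--topk", default=10, show_default=True, type=int)
@click.option("--out", "out_path", default=None, help="Write TSV here (default stdout).")
@click.option(
    "--seed-check",
    is_flag=True,
    help="Re-score the top hit with the scalar reference engine and fail on mismatch.",
)
def main(
    query_path,
    db_path,
    matrix,
    gap_spec,
    gap_open,
    gap_extend,
    engine,
    vl,
    pl,
    topk,
    out_path,
    seed_check,
):
    """Smith-Waterman protein database search with exact scores."""
    try:
        gap = parse_gap_spec(gap_spec) if gap_spec else GapPenalty(gap_open, gap_extend)
        scheme = ScoringScheme(load_matrix(matrix), gap)
    except (GapSpecError, ValueError) as exc:
        raise click.UsageError(str(exc)) from exc  # exit code 2
    except MatrixFormatError as exc:
        click.echo(f"swsearch: {exc}", err=True)
        sys.exit(EXIT_INPUT)
    try:
        queries = read_fasta(query_path)
        db = read_fasta(db_path)
        result = search(
            queries[0], db, scheme, engine=engine, VL=vl, PL=pl, topk=topk
        )
    except (InputFormatError, ValueError) as exc:
        click.echo(f"swsearch: {exc}", err=True)
        sys.exit(EXIT_INPUT)

    if seed_check and result.hits:
        top = result.hits[0]
        ref = sw_score(
            queries[0].sequence,
            next(r.sequence for r in db if r.id == top.subject_id),
            scheme,
        )
        if ref != top.score:
            click.echo(
                f"swsearch: self-check FAILED: engine={engine} scored "
                f"{top.score} but scalar reference gives {ref}",
                err=True,
            )
            sys.exit(1)
        click.echo(
            f"# self-check ok: top hit {top.subject_id} score {top.score} "
            "confirmed by scalar engine",
            err=True,
        )

    if out_path:
        with open(out_path, "w") as fh:
            result.write_tsv(fh)
    else:
        result.write_tsv(sys.stdout)


if __name__ == "__main__":
    main()
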
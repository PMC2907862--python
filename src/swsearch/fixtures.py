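"""Seeded synthetic protein sequences, so nothing ever needs downloading.

The generator draws residues i.i.d. from a composition over the 20 standard
amino acids (uniform by default; a Swiss-Prot-like table is available for
realism). ``mutate_homolog`` derives related sequences — point substitutions
plus geometric-length indels — so searches against synthetic databases have
genuine diagonal signal. Everything is deterministic given (spec, seed): the
same call reproduces the same FASTA file byte for byte, and no global random
state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import click
import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "SWISSPROT_LIKE_COMPOSITION",
    "FixtureSpec",
    "random_protein",
    "mutate_homolog",
    "generate_database",
    "main",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: rough database-wide amino-acid frequencies of curated protein sets;
#: optional realism knob, never required by any test
SWISSPROT_LIKE_COMPOSITION = {
    "A": 0.083, "C": 0.014, "D": 0.055, "E": 0.067, "F": 0.039,
    "G": 0.071, "H": 0.023, "I": 0.059, "K": 0.058, "L": 0.097,
    "M": 0.024, "N": 0.041, "P": 0.047, "Q": 0.039, "R": 0.055,
    "S": 0.066, "T": 0.053, "V": 0.069, "W": 0.011, "Y": 0.029,
}

#: geometric success parameter for indel event lengths (mean length 2)
_INDEL_GEOM_P = 0.5


def _composition_arrays(composition=None):
    if composition is None:
        letters = np.array(list(AMINO_ACIDS))
        probs = np.full(len(letters), 1.0 / len(letters))
    else:
        letters = np.array(list(composition.keys()))
        probs = np.array(list(composition.values()), dtype=float)
        if (probs < 0).any() or probs.sum() <= 0:
            raise ValueError("composition must be non-negative and sum > 0")
        probs = probs / probs.sum()
    return letters, probs


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_protein(length: int, seed, composition=None) -> str:
    """I.i.d. residue string of the given length; deterministic per seed."""
    if length < 0:
        raise ValueError(f"length must be >= 0, got {length}")
    letters, probs = _composition_arrays(composition)
    rng = _rng(seed)
    return "".join(rng.choice(letters, size=length, p=probs))


def mutate_homolog(
    sequence: str, substitution_rate: float, indel_rate: float, seed
) -> str:
    """Derive a homolog by point substitutions and geometric-length indels.

    Each position is independently substituted (to a *different* residue)
    with probability ``substitution_rate``; before each position an indel
    event starts with probability ``indel_rate`` and is an insertion or a
    deletion (equal odds) of geometric length (mean 2).
    """
    for name, rate in (("substitution", substitution_rate), ("indel", indel_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} rate must be in [0, 1], got {rate}")
    letters, probs = _composition_arrays(None)
    rng = _rng(seed)
    out: list[str] = []
    i = 0
    n = len(sequence)
    while i < n:
        if indel_rate > 0 and rng.random() < indel_rate:
            k = int(rng.geometric(_INDEL_GEOM_P))
            if rng.random() < 0.5:  # insertion
                out.extend(rng.choice(letters, size=k, p=probs))
            else:  # deletion
                i += k
                continue
        ch = sequence[i]
        if substitution_rate > 0 and rng.random() < substitution_rate:
            pool = [c for c in letters if c != ch] or [ch]
            ch = pool[int(rng.integers(len(pool)))]
        out.append(ch)
        i += 1
    return "".join(out)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic database; (spec, seed) fixes the output bytes.

    ``length_law`` is ``("fixed", L)``, ``("uniform", a, b)`` or
    ``("loguniform", a, b)`` (inclusive bounds).
    """

    n_records: int
    length_law: tuple
    seed: int
    composition: dict | None = None

    def draw_length(self, rng: np.random.Generator) -> int:
        law = self.length_law[0]
        if law == "fixed":
            return int(self.length_law[1])
        a, b = int(self.length_law[1]), int(self.length_law[2])
        if a > b or a < 1:
            raise ValueError(f"bad length bounds {self.length_law}")
        if law == "uniform":
            return int(rng.integers(a, b + 1))
        if law == "loguniform":
            return int(round(np.exp(rng.uniform(np.log(a), np.log(b)))))
        raise ValueError(f"unknown length law {law!r}")


def generate_database(spec: FixtureSpec, path: str | Path) -> Path:
    """Write ``spec.n_records`` synthetic FASTA records; fully reproducible."""
    path = Path(path)
    lines: list[str] = []
    for i in range(spec.n_records):
        # independent child streams per record: record i never depends on
        # how many records precede it
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), i]))
        length = spec.draw_length(rng)
        letters, probs = _composition_arrays(spec.composition)
        seq = "".join(rng.choice(letters, size=length, p=probs))
        lines.append(f">synth_{i} len={length} seed={spec.seed}")
        lines.extend(seq[k : k + 60] for k in range(0, length, 60))
    path.write_text("\n".join(lines) + "\n")
    return path


def _parse_length_law(text: str) -> tuple:
    parts = text.split(":")
    law = parts[0].lower()
    if law == "fixed" and len(parts) == 2:
        return ("fixed", int(parts[1]))
    if law in ("uniform", "loguniform") and len(parts) == 3:
        return (law, int(parts[1]), int(parts[2]))
    raise ValueError(
        f"cannot parse length law {text!r}; expected fixed:L, uniform:a:b "
        "or loguniform:a:b"
    )


@click.command(name="swsearch-fixtures")
@click.option("--n", "n_records", required=True, type=int)
@click.option("--lengths", "lengths", default="uniform:100:400", show_default=True)
@click.option("--seed", default=42, show_default=True, type=int)
@click.option("--out", "out_path", required=True)
@click.option(
    "--composition",
    type=click.Choice(["uniform", "swissprot"]),
    default="uniform",
    show_default=True,
)
def main(n_records, lengths, seed, out_path, composition):
    """Generate a seeded synthetic protein FASTA database."""
    try:
        law = _parse_length_law(lengths)
    except ValueError as exc:
        raise click.UsageError(str(exc)) from exc
    spec = FixtureSpec(
        n_records=n_records,
        length_law=law,
        seed=seed,
        composition=SWISSPROT_LIKE_COMPOSITION
        if composition == "swissprot"
        else None,
    )
    generate_database(spec, out_path)
    click.echo(f"wrote {n_records} records to {out_path}")


if __name__ == "__main__":
    main()
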
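"""6mer seed primitives and the per-seed viability lookup.

The 6mer seed of a guide-strand small RNA is the hexamer at 1-based
positions 2-7.  Its *viability* is the mean percent viability of cells
transfected with an siRNA-like duplex carrying that seed, screened in
three human and three mouse cell lines; per-species averages (human or
mouse) are the values every downstream statistic consumes.  Viability is
kept on the percent scale throughout (40.0, not 0.40), and values above
100 are legal: some seeds enhance growth.
"""

from __future__ import annotations

import itertools
from os import PathLike
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import AlphabetError, ReadTooShortError, ViabilityTableError

SEED_LENGTH = 6
N_SEEDS = 4**SEED_LENGTH  # 4096
RNA_ALPHABET = frozenset("ACGU")

Species = Literal["human", "mouse"]
SPECIES: tuple[str, ...] = ("human", "mouse")

#: default cell-line column names of the viability CSV (three per species)
HUMAN_COLUMNS: tuple[str, ...] = ("human_line1", "human_line2", "human_line3")
MOUSE_COLUMNS: tuple[str, ...] = ("mouse_line1", "mouse_line2", "mouse_line3")

_TO_RNA = str.maketrans("acgtuACGTU", "ACGUUACGUU")


def normalize_sequence(seq: str) -> str:
    """Uppercase ``seq`` and map T to U, validating the alphabet.

    All pipeline stages key tables by RNA-space sequences, so DNA-space
    sequencing reads are converted once at ingestion.
    """
    norm = seq.translate(_TO_RNA)
    if not RNA_ALPHABET.issuperset(norm):
        bad = sorted(set(norm) - RNA_ALPHABET)
        raise AlphabetError(f"illegal characters {bad} in sequence {seq!r}")
    return norm


def all_seeds() -> list[str]:
    """Enumerate the full seed space: all 4096 hexamers over {A,C,G,U}."""
    return ["".join(p) for p in itertools.product("ACGU", repeat=SEED_LENGTH)]


def extract_seed(read: str) -> str:
    """Return the 6mer seed (1-based positions 2-7) of a guide-strand read.

    The read is alphabet-normalized first, so ``"tggcagtgtcttag"`` and
    ``"UGGCAGUGUCUUAG"`` both yield ``"GGCAGU"``.

    Raises
    ------
    ReadTooShortError
        If the read is shorter than 7 nt (callers drop such rows).
    AlphabetError
        If the read contains non-nucleotide characters.
    """
    norm = normalize_sequence(read)
    if len(norm) < SEED_LENGTH + 1:
        raise ReadTooShortError(
            f"read {read!r} is {len(norm)} nt; need >= 7 for a position 2-7 seed"
        )
    return norm[1 : SEED_LENGTH + 1]


class ViabilityTable:
    """Complete per-seed viability lookup for six cell lines.

    Wraps a DataFrame indexed by seed with one column per cell line
    (three human, three mouse) and exposes per-species averages.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        human_columns: Sequence[str] = HUMAN_COLUMNS,
        mouse_columns: Sequence[str] = MOUSE_COLUMNS,
    ) -> None:
        if len(human_columns) != 3 or len(mouse_columns) != 3:
            raise ViabilityTableError("expected three cell-line columns per species")
        missing_cols = [c for c in (*human_columns, *mouse_columns) if c not in frame.columns]
        if missing_cols:
            raise ViabilityTableError(f"missing cell-line columns: {missing_cols}")

        seeds = frame.index.astype(str)
        dup = seeds[seeds.duplicated()]
        if len(dup):
            raise ViabilityTableError(f"duplicate seeds: {sorted(set(dup))[:5]}")
        for s in seeds:
            if len(s) != SEED_LENGTH or not RNA_ALPHABET.issuperset(s):
                raise ViabilityTableError(f"bad alphabet or length in seed {s!r}")
        if len(seeds) != N_SEEDS:
            absent = sorted(set(all_seeds()) - set(seeds))
            raise ViabilityTableError(
                f"viability table has {len(seeds)} seeds, expected {N_SEEDS};"
                f" first missing: {absent[:3]}"
            )

        values = frame[list(human_columns) + list(mouse_columns)].astype(float)
        if values.isna().any().any():
            raise ViabilityTableError("viability table contains missing values")
        if (values.to_numpy() < 0).any():
            bad = values.index[(values.to_numpy() < 0).any(axis=1)][0]
            raise ViabilityTableError(f"negative viability for seed {bad}")

        self._frame = values.copy()
        self._frame.index = pd.Index(seeds, name="seed")
        self._frame.sort_index(inplace=True)
        self._human_columns = tuple(human_columns)
        self._mouse_columns = tuple(mouse_columns)
        self._averages = pd.DataFrame(
            {
                "human": self._frame[list(human_columns)].mean(axis=1),
                "mouse": self._frame[list(mouse_columns)].mean(axis=1),
            }
        )

    def __len__(self) -> int:
        return len(self._frame)

    @property
    def frame(self) -> pd.DataFrame:
        """Per-cell-line viability values, seed-indexed, sorted."""
        return self._frame

    def species_average(self, species: Species) -> pd.Series:
        """Seed-indexed Series of the species' three-cell-line mean viability."""
        if species not in SPECIES:
            raise ViabilityTableError(f"unknown species {species!r}; expected {SPECIES}")
        return self._averages[species]

    def lookup(self, seed: str, species: Species) -> float:
        avg = self.species_average(species)
        try:
            return float(avg.loc[seed])
        except KeyError:
            raise ViabilityTableError(
                f"seed {seed!r} absent from viability table (table incomplete)"
            ) from None

    def to_csv(self, path: str | PathLike) -> None:
        out = self._frame.copy()
        out.columns = list(self._human_columns) + list(self._mouse_columns)
        out.to_csv(path, float_format="%.4f")


def seed_viability(seed: str, species: Species, table: ViabilityTable) -> float:
    """Species-average percent viability of ``seed`` (mean of three lines)."""
    return table.lookup(normalize_sequence(seed), species)


def load_viability_table(
    path: str | PathLike,
    seed_column: str = "seed",
    human_columns: Sequence[str] = HUMAN_COLUMNS,
    mouse_columns: Sequence[str] = MOUSE_COLUMNS,
) -> ViabilityTable:
    """Read and validate a viability CSV (header row, one row per seed).

    Completeness (4096 seeds), alphabet, duplicates and non-negativity are
    all enforced; failures name the offending seed or column.
    """
    frame = pd.read_csv(path)
    if seed_column not in frame.columns:
        raise ViabilityTableError(f"seed column {seed_column!r} not in {path}")
    try:
        seeds = [normalize_sequence(s) for s in frame[seed_column].astype(str)]
    except AlphabetError as exc:
        raise ViabilityTableError(f"bad alphabet in seed column of {path}: {exc}") from exc
    frame = frame.set_index(pd.Index(seeds, name="seed"))
    return ViabilityTable(frame, human_columns, mouse_columns)
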
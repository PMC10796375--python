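"""Synthetic data generator for the whole pipeline.

Emulates the statistical structure of an Ago pulldown small-RNA
sequencing experiment: a complete 4096-entry seed-viability screen in
which G-rich seeds are toxic, two-group read count tables whose
perturbed group is tilted toward low-viability seeds with a controlled
strength, matching reference FASTA sets, and per-sample FASTQ files that
invert exactly through preprocessing.  Every operation is deterministic
under its ``rng_seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotate import ReferenceSet
from .errors import ConfigError
from .preprocess import sort_count_table
from .seedcore import (
    HUMAN_COLUMNS,
    MOUSE_COLUMNS,
    Species,
    ViabilityTable,
    all_seeds,
    normalize_sequence,
)

logger = logging.getLogger(__name__)

#: standard small-RNA 3' adapter (RNA space)
DEFAULT_ADAPTER = "UGGAAUUCUCGGGUGCCAAGG"

_NTS = np.array(list("ACGU"))


def gen_viability_table(rng_seed: int = 0) -> ViabilityTable:
    """Simulate the 4096-seed viability screen across six cell lines.

    Base viability decreases monotonically with a G/C-weighted content
    score (G counts double C: G-rich seeds are the toxic ones), with
    independent per-cell-line Gaussian noise, clipped at 0.  A-rich seeds
    regularly exceed 100% — growth-enhancing seeds exist.
    """
    rng = np.random.default_rng(rng_seed)
    seeds = all_seeds()
    n_g = np.array([s.count("G") for s in seeds], dtype=float)
    n_c = np.array([s.count("C") for s in seeds], dtype=float)
    base = 105.0 - 12.0 * n_g - 5.0 * n_c
    values = base[:, None] + rng.normal(0.0, 8.0, size=(len(seeds), 6))
    np.clip(values, 0.0, None, out=values)
    frame = pd.DataFrame(
        values, index=pd.Index(seeds, name="seed"),
        columns=list(HUMAN_COLUMNS) + list(MOUSE_COLUMNS),
    )
    return ViabilityTable(frame)


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a simulated two-group Ago pulldown experiment.

    ``shift`` in [-1, 1] tilts the perturbed group's RISC loading toward
    low-viability (G-rich) seeds; 0 is the exchangeable null.  Depth is
    the expected raw reads per sample.  RNA-type fractions may sum to
    less than 1; the remainder is unannotated ("unknown") reads.
    """

    rng_seed: int = 0
    n_rows: int = 300
    samples_per_group: int = 3
    depth: float = 1e5
    shift: float = 0.0
    species: Species = "mouse"
    fraction_mirna: float = 0.5
    fraction_rnaworld: float = 0.25
    fraction_artificial: float = 0.05
    adapter: str = DEFAULT_ADAPTER
    min_read_length: int = 18
    max_read_length: int = 24

    def __post_init__(self) -> None:
        fracs = (self.fraction_mirna, self.fraction_rnaworld, self.fraction_artificial)
        if any(not 0.0 <= f <= 1.0 for f in fracs) or sum(fracs) > 1.0:
            raise ConfigError("rna-type fractions must lie in [0,1] and sum to <= 1")
        if self.samples_per_group < 2:
            raise ConfigError(
                "samples_per_group must be >= 2 (differential selection needs"
                " within-group variance)"
            )
        if not -1.0 <= self.shift <= 1.0:
            raise ConfigError("shift must lie in [-1, 1]")
        if self.n_rows < 1 or self.depth <= 0:
            raise ConfigError("n_rows must be >= 1 and depth > 0")
        if not 7 <= self.min_read_length <= self.max_read_length:
            raise ConfigError("read lengths must satisfy 7 <= min <= max")

    def sample_groups(self) -> dict[str, list[str]]:
        k = self.samples_per_group
        return {
            "control": [f"control_{i+1}" for i in range(k)],
            "perturbed": [f"perturbed_{i+1}" for i in range(k)],
        }


@dataclass(frozen=True)
class GroundTruth:
    """Per-row truth of a simulated experiment plus the injected effect."""

    frame: pd.DataFrame  # index sequence; seed, rna_type, viability, lam_control, lam_perturbed
    shift: float
    species: Species

    @property
    def expected_median_sign(self) -> int:
        """Sign of (perturbed median viability - control median); 0 under the null."""
        if self.shift > 0:
            return -1
        if self.shift < 0:
            return 1
        return 0


def _draw_sequences(
    rng: np.random.Generator, seeds: list[str], cfg: SimulationConfig
) -> list[str]:
    """One unique read per seed, seed at positions 2-7, random flanks.

    Rejects candidates that contain the full adapter (so trimming could
    never fire inside an insert; partial internal matches are harmless
    because the generator always appends the complete, aperiodic
    adapter) or that stand in a substring relation with an
    already-accepted read (so exact-substring reference matching
    recovers planted annotations exactly).
    """
    accepted: list[str] = []
    for seed in seeds:
        while True:
            length = int(rng.integers(cfg.min_read_length, cfg.max_read_length + 1))
            head = str(rng.choice(_NTS))
            tail = "".join(rng.choice(_NTS, size=length - 7))
            candidate = head + seed + tail
            if cfg.adapter in candidate:
                continue
            if any(candidate in a or a in candidate for a in accepted):
                continue
            accepted.append(candidate)
            break
    return accepted


def gen_counts(
    cfg: SimulationConfig, viab: ViabilityTable
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a two-group raw count table with a controlled viability shift.

    Row identities embed distinct seeds at positions 2-7; baseline
    abundances are heavy-tailed (lognormal); the perturbed group's
    expected loading is multiplied by exp(shift * (50 - viability) / 25)
    and renormalized, so shift > 0 enriches low-viability seeds.  Integer
    counts are Poisson around group means scaled to the target depth.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    seed_space = all_seeds()
    replace = cfg.n_rows > len(seed_space)
    seeds = list(rng.choice(seed_space, size=cfg.n_rows, replace=replace))
    sequences = _draw_sequences(rng, seeds, cfg)

    labels = np.array(["miRNA", "RNAworld", "artificial", "unknown"])
    probs = np.array(
        [
            cfg.fraction_mirna,
            cfg.fraction_rnaworld,
            cfg.fraction_artificial,
            1.0 - cfg.fraction_mirna - cfg.fraction_rnaworld - cfg.fraction_artificial,
        ]
    )
    rna_types = rng.choice(labels, size=cfg.n_rows, p=probs)

    viability = viab.species_average(cfg.species).reindex(seeds).to_numpy()
    base = rng.lognormal(mean=3.0, sigma=1.5, size=cfg.n_rows)
    tilt = np.exp(cfg.shift * (50.0 - viability) / 25.0)
    lam_control = cfg.depth * base / base.sum()
    lam_perturbed = cfg.depth * (base * tilt) / (base * tilt).sum()

    groups = cfg.sample_groups()
    counts = {}
    for sample in groups["control"]:
        counts[sample] = rng.poisson(lam_control)
    for sample in groups["perturbed"]:
        counts[sample] = rng.poisson(lam_perturbed)
    table = pd.DataFrame(counts, index=pd.Index(sequences, name="sequence"))
    table = sort_count_table(table)

    truth = pd.DataFrame(
        {
            "seed": seeds,
            "rna_type": rna_types,
            "viability": viability,
            "lam_control": lam_control,
            "lam_perturbed": lam_perturbed,
        },
        index=pd.Index(sequences, name="sequence"),
    ).loc[table.index]
    return table, GroundTruth(frame=truth, shift=cfg.shift, species=cfg.species)


def gen_references(
    truth: GroundTruth, rng_seed: int = 0
) -> dict[str, ReferenceSet]:
    """Build the three reference sets matching a simulated experiment.

    miRNA references are the simulated miRNA reads themselves under
    synthetic names; RNAworld references are longer host sequences that
    contain the simulated fragments; artificial references are the
    decoy reads planted by the generator (exactly the rows annotation
    must remove).
    """
    rng = np.random.default_rng(rng_seed)
    frame = truth.frame
    all_rows = list(frame.index)

    mirna_records = []
    rnaworld_records = []
    artificial_records = []
    for i, (seq, row) in enumerate(frame.iterrows()):
        if row["rna_type"] == "miRNA":
            mirna_records.append((f"syn-miR-{i}-5p", seq))
        elif row["rna_type"] == "RNAworld":
            others = [s for s in all_rows if s != seq]
            for _ in range(50):
                flank5 = "".join(rng.choice(_NTS, size=int(rng.integers(10, 21))))
                flank3 = "".join(rng.choice(_NTS, size=int(rng.integers(10, 21))))
                host = flank5 + seq + flank3
                if not any(o in host for o in others):
                    break
            else:  # pragma: no cover - vanishingly unlikely
                raise RuntimeError("could not draw a collision-free host sequence")
            rnaworld_records.append((f"syn-rw-{i}", host))
        elif row["rna_type"] == "artificial":
            artificial_records.append((f"syn-art-{i}", seq))

    refs = {
        "artificial": ReferenceSet("artificial", tuple(artificial_records)),
        "miRNA": ReferenceSet("miRNA", tuple(mirna_records)),
        "RNAworld": ReferenceSet("RNAworld", tuple(rnaworld_records)),
    }
    for mi_name, mi_seq in refs["miRNA"].records:
        for _, art_seq in refs["artificial"].records:
            if mi_seq in art_seq:  # pragma: no cover - excluded at generation
                raise RuntimeError(f"miRNA reference {mi_name} inside artificial set")
    return refs


def gen_fastq(
    table: pd.DataFrame,
    adapter: str,
    rng_seed: int,
    outdir: str | PathLike,
) -> dict[str, Path]:
    """Materialize per-sample FASTQ files inverting to ``table``.

    Each row's sequence (DNA space) plus the 3' adapter is emitted once
    per raw count, deterministically shuffled.  Running preprocessing on
    the result reproduces ``table`` exactly (for rows passing the
    rare-read filter).
    """
    rng = np.random.default_rng(rng_seed)
    adapter_dna = normalize_sequence(adapter).replace("U", "T")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sample in table.columns:
        reads = np.repeat(
            table.index.to_numpy(), table[sample].to_numpy(dtype=np.int64)
        )
        rng.shuffle(reads)
        path = outdir / f"{sample}.fastq"
        with open(path, "w") as handle:
            for i, seq in enumerate(reads):
                full = seq.replace("U", "T") + adapter_dna
                handle.write(f"@{sample}:{i}\n{full}\n+\n{'I' * len(full)}\n")
        paths[sample] = path
    return paths
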
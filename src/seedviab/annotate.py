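"""Reference matching and seed/viability annotation of count tables.

Each read is assigned an RNA type by exact-substring containment against
ordered reference sets: artificial spike/adapter sequences (highest
priority, matching rows are removed), mature miRNAs, then an "RNAworld"
catch-all of other small RNAs (tRNA/rRNA fragments etc.).  Unmatched
reads are kept as type ``unknown`` — the analysis is gene-agnostic and
every read with >= 7 nt carries a seed and a viability regardless of its
annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import AnnotationError, ReadTooShortError
from .seedcore import Species, ViabilityTable, extract_seed, normalize_sequence

logger = logging.getLogger(__name__)

#: reference-set priority, highest first; artificial matches are removed
PRIORITY_ORDER = ("artificial", "miRNA", "RNAworld")

ANNOTATION_COLUMNS = ("rna_type", "match_name", "seed", "viability")


@dataclass(frozen=True)
class ReferenceSet:
    """Named reference sequences with a fixed matching priority.

    ``records`` preserve file order; ties among references within a set
    resolve to the first record.
    """

    name: str
    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.name not in PRIORITY_ORDER:
            raise AnnotationError(
                f"reference set name {self.name!r} not one of {PRIORITY_ORDER}"
            )
        names = [n for n, _ in self.records]
        if len(names) != len(set(names)):
            dup = next(n for n in names if names.count(n) > 1)
            raise AnnotationError(f"duplicate reference name {dup!r} in set {self.name}")

    @property
    def priority(self) -> int:
        return PRIORITY_ORDER.index(self.name)

    def find(self, read: str) -> str | None:
        """Name of the first reference containing ``read`` as a substring."""
        for ref_name, ref_seq in self.records:
            if read in ref_seq:
                return ref_name
        return None


def load_reference_fasta(path: str | PathLike, name: str) -> ReferenceSet:
    """Load a reference set from FASTA, normalizing sequences to RNA space."""
    records = tuple(
        (record.id, normalize_sequence(str(record.seq)))
        for record in SeqIO.parse(str(path), "fasta")
    )
    return ReferenceSet(name=name, records=records)


def write_reference_fasta(refset: ReferenceSet, path: str | PathLike) -> None:
    with open(path, "w") as handle:
        for ref_name, ref_seq in refset.records:
            handle.write(f">{ref_name}\n{ref_seq}\n")


def match_read(read: str, refs: Sequence[ReferenceSet]) -> tuple[str, str]:
    """Assign ``(rna_type, match_name)`` by priority-ordered containment.

    Returns ``("unknown", "")`` when no set contains the read.
    """
    for refset in sorted(refs, key=lambda r: r.priority):
        hit = refset.find(read)
        if hit is not None:
            return refset.name, hit
    return "unknown", ""


def annotate_table(
    table: pd.DataFrame,
    refs: Sequence[ReferenceSet],
    species: Species,
    viab: ViabilityTable,
) -> pd.DataFrame:
    """Attach rna_type, match_name, seed and viability to a count table.

    Rows matching an artificial reference and rows shorter than 7 nt are
    removed (counts logged); count values of surviving rows are never
    changed.  Annotation columns are appended after the sample columns.
    """
    rna_types: list[str] = []
    match_names: list[str] = []
    keep: list[bool] = []
    n_artificial = 0
    n_short = 0
    for seq in table.index:
        if len(seq) < 7:
            n_short += 1
            keep.append(False)
            rna_types.append("")
            match_names.append("")
            continue
        rna_type, match_name = match_read(seq, refs)
        if rna_type == "artificial":
            n_artificial += 1
            keep.append(False)
        else:
            keep.append(True)
        rna_types.append(rna_type)
        match_names.append(match_name)
    if n_artificial:
        logger.info("annotate_table removed %d artificial-matching rows", n_artificial)
    if n_short:
        logger.info("annotate_table removed %d rows shorter than 7 nt", n_short)

    out = table.loc[keep].copy()
    out["rna_type"] = [t for t, k in zip(rna_types, keep) if k]
    out["match_name"] = [m for m, k in zip(match_names, keep) if k]
    seeds = [extract_seed(seq) for seq in out.index]
    out["seed"] = seeds
    avg = viab.species_average(species)
    out["viability"] = avg.reindex(seeds).to_numpy()
    return out


def annotate_mirna_list(
    names_and_values: Iterable[tuple[str, float]],
    mirna_ref: ReferenceSet,
    species: Species,
    viab: ViabilityTable,
) -> pd.DataFrame:
    """Annotate a published miRNA list (name, value) directly from references.

    The entry mode for reanalyzing differential miRNA lists: each name is
    resolved against the mature-miRNA reference, the seed is read from
    positions 2-7 of the stored mature sequence, and the provided value
    becomes the single ``weight`` column (its sign encodes direction:
    positive = upregulated).
    """
    lookup = dict(mirna_ref.records)
    pairs = list(names_and_values)
    missing = sorted({name for name, _ in pairs if name not in lookup})
    if missing:
        raise AnnotationError(f"miRNA names not in reference: {missing}")
    rows = []
    for name, value in pairs:
        seq = lookup[name]
        rows.append(
            {
                "sequence": seq,
                "weight": float(value),
                "rna_type": "miRNA",
                "match_name": name,
                "seed": extract_seed(seq),
            }
        )
    out = pd.DataFrame(rows).set_index("sequence")
    out["viability"] = viab.species_average(species).reindex(out["seed"]).to_numpy()
    return out


def sample_columns(annotated: pd.DataFrame) -> list[str]:
    """Columns of an annotated table that hold per-sample counts."""
    return [c for c in annotated.columns if c not in ANNOTATION_COLUMNS]
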
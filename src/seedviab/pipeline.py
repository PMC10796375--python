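"""Report assembly: the two entry modes of the analysis.

``run_full`` drives FASTQ (or a precomputed count table) through
preprocessing, annotation, normalization, differential selection and the
viability statistics, writing every intermediate table, the statistics
TSVs and a run manifest.  ``run_mirna_list`` is the entry mode for
reanalyzing published differential miRNA lists (name/value pairs).
Outputs are deterministic: identical config and inputs give
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from os import PathLike
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .annotate import (
    ReferenceSet,
    annotate_mirna_list,
    annotate_table,
    load_reference_fasta,
    sample_columns,
)
from .config import PipelineConfig
from .diffstats import DifferentialResult, differential, normalize_counts, write_differential
from .errors import ConfigError, SeedViabError
from .preprocess import fastq_to_counts, filter_rare, read_count_table, write_count_table
from .seedcore import load_viability_table
from .viabstats import (
    QUANTILE_CONVENTION,
    ExpansionConfig,
    binned_curve,
    box_stats,
    box_stats_frame,
    compare_groups,
    expand,
    seed_composition,
    split_differential,
)

logger = logging.getLogger(__name__)


def _sha256(path: str | PathLike) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


class _Workspace:
    """Tracks written outputs so a failed stage can clean up after itself."""

    def __init__(self, outdir: str | PathLike) -> None:
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.written: list[Path] = []

    def path(self, name: str) -> Path:
        path = self.outdir / name
        self.written.append(path)
        return path

    def discard(self) -> None:
        for path in self.written:
            path.unlink(missing_ok=True)


def _load_references(config: PipelineConfig) -> list[ReferenceSet]:
    return [
        load_reference_fasta(path, name) for name, path in config.references.items()
    ]


def _group_mean_column(norm: pd.DataFrame, samples: list[str], name: str) -> pd.DataFrame:
    out = norm.copy()
    out[name] = norm[samples].mean(axis=1)
    return out


def _stats_block(
    ws: _Workspace,
    tables: Mapping[str, pd.DataFrame],
    weight_columns: Mapping[str, str],
    tag: str,
    ecfg: ExpansionConfig,
    bin_width: float,
) -> dict:
    """Box stats + comparison + curves + compositions for a set of groups."""
    expanded = {}
    for name, table in tables.items():
        ev = expand(table, weight_columns[name], ecfg, provenance=f"{tag}:{name}")
        if ev.n:
            expanded[name] = ev
        else:
            logger.warning("%s group %r expanded to an empty multiset", tag, name)

    stats_by_group = {name: box_stats(ev) for name, ev in expanded.items()}
    frame = box_stats_frame(stats_by_group)
    if len(expanded) >= 2:
        h, p = compare_groups(list(expanded.values()))
        frame["kruskal_H"] = h
        frame["kruskal_p"] = p
    frame.to_csv(ws.path(f"boxstats_{tag}.tsv"), sep="\t", index=False,
                 float_format="%.10g")

    curves = []
    comps = {}
    for name, table in tables.items():
        curve = binned_curve(table, weight_columns[name], bin_width)
        curve.insert(0, "group", name)
        curves.append(curve)
        try:
            comp = seed_composition(table, weight_columns[name], ecfg)
        except ValueError:
            continue
        comps[name] = comp
        comp.to_csv(ws.path(f"composition_{tag}_{name}.tsv"), sep="\t",
                    float_format="%.10g")
    if curves:
        pd.concat(curves, ignore_index=True).to_csv(
            ws.path(f"curve_{tag}.tsv"), sep="\t", index=False, float_format="%.10g"
        )
    return {
        "expanded": expanded,
        "box_stats": stats_by_group,
        "frame": frame,
        "compositions": comps,
    }


def run_full(config: PipelineConfig, outdir: str | PathLike) -> dict:
    """Run the whole analysis and materialize a workspace of outputs.

    Writes rawCounts/normCounts/annotated/differential TSVs, box-stat,
    curve and composition tables for the total-RNA and differential
    modes, and a manifest recording every config value, input checksum,
    software version and dropped-row accounting.  Any stage failure
    removes partial outputs and re-raises with the stage name.
    """
    config.validate()
    if config.viability_csv is None:
        raise ConfigError("viability_csv is required")
    if config.counts_table is None and not config.fastq:
        raise ConfigError("either counts_table or fastq inputs are required")

    ws = _Workspace(outdir)
    accounting: dict = {}
    stage = "setup"
    try:
        stage = "viability"
        viab = load_viability_table(config.viability_csv)

        stage = "preprocess"
        if config.counts_table is not None:
            raw = read_count_table(config.counts_table)
            n_input = len(raw)
            raw = filter_rare(raw, config.min_total)
        else:
            raw, trim_stats = fastq_to_counts(
                config.fastq, config.adapter, config.min_overlap, config.min_total
            )
            n_input = len(raw)  # post-filter; per-read accounting below
            accounting["trim"] = {s: vars(st) for s, st in trim_stats.items()}
        accounting["rows_after_rare_filter"] = len(raw)
        known = [s for g in config.groups.values() for s in g]
        missing = [s for s in known if s not in raw.columns]
        if missing:
            raise ConfigError(f"samples in group map absent from counts: {missing}")
        raw = raw[known]
        write_count_table(raw, ws.path("rawCounts.tsv"))

        stage = "annotate"
        refs = _load_references(config)
        annotated = annotate_table(raw, refs, config.species, viab)
        accounting["rows_removed_by_annotation"] = len(raw) - len(annotated)
        write_count_table(annotated, ws.path("annotated.tsv"))

        stage = "normalize"
        norm = normalize_counts(annotated)
        write_count_table(norm, ws.path("normCounts.tsv"))

        ecfg = ExpansionConfig(divisor=config.divisor)

        stage = "stats-total"
        total_tables = {}
        total_weights = {}
        for group, samples in config.groups.items():
            col = f"mean_{group}"
            total_tables[group] = _group_mean_column(norm, samples, col)
            total_weights[group] = col
        total = _stats_block(ws, total_tables, total_weights, "total", ecfg,
                             config.bin_width)

        stage = "differential"
        result = differential(
            norm,
            config.groups[config.control_group],
            config.groups[config.perturbed_group],
            config.alpha,
            config.test,  # type: ignore[arg-type]
        )
        accounting["differential_rows_tested"] = result.n_tested
        accounting["differential_rows_skipped_constant"] = result.n_skipped_constant
        accounting["differential_rows_retained"] = len(result.table)
        write_differential(result, ws.path("differential.tsv"))

        stage = "stats-differential"
        enriched, depleted = split_differential(result.table)
        diff_tables = {"enriched": enriched, "depleted": depleted}
        diff_weights = {"enriched": "weight", "depleted": "weight"}
        diff = _stats_block(ws, diff_tables, diff_weights, "differential", ecfg,
                            config.bin_width)

        stage = "manifest"
        manifest = {
            "seedviab_version": __version__,
            "config": config.to_dict(),
            "quantile_convention": QUANTILE_CONVENTION,
            "statistical_test": f"{config.test} t-test, two-sided, no multiple-testing correction",
            "inputs": {
                name: _sha256(path)
                for name, path in {
                    "viability_csv": config.viability_csv,
                    "counts_table": config.counts_table,
                    **{f"fastq:{s}": p for s, p in config.fastq.items()},
                    **{f"reference:{n}": p for n, p in config.references.items()},
                }.items()
                if path is not None
            },
            "accounting": accounting,
        }
        with open(ws.path("manifest.json"), "w") as handle:
            json.dump(manifest, handle, indent=2, sort_keys=True)
            handle.write("\n")
    except Exception as exc:
        ws.discard()
        raise SeedViabError(f"stage {stage!r} failed: {exc}") from exc

    return {
        "outdir": ws.outdir,
        "raw": raw,
        "annotated": annotated,
        "norm": norm,
        "differential": result,
        "total": total,
        "diff_stats": diff,
        "manifest": manifest,
    }


def run_mirna_list(
    csv_path: str | PathLike, config: PipelineConfig, outdir: str | PathLike
) -> dict:
    """Reanalyze a published miRNA list (2-column CSV: name, value).

    The sign of the value encodes direction (positive = upregulated);
    |value| is the expansion weight.  Writes the annotated table, box
    stats per direction (with group comparison when both directions are
    present) and composition matrices per direction.
    """
    config.validate()
    if config.viability_csv is None:
        raise ConfigError("viability_csv is required")
    mirna_path = config.references.get("miRNA")
    if mirna_path is None:
        raise ConfigError("a miRNA reference FASTA is required for list mode")

    ws = _Workspace(outdir)
    stage = "setup"
    try:
        stage = "viability"
        viab = load_viability_table(config.viability_csv)
        stage = "annotate-list"
        listing = pd.read_csv(csv_path)
        if listing.shape[1] < 2:
            raise ConfigError("miRNA list CSV needs (name, value) columns")
        pairs = list(zip(listing.iloc[:, 0].astype(str), listing.iloc[:, 1].astype(float)))
        mirna_ref = load_reference_fasta(mirna_path, "miRNA")
        annotated = annotate_mirna_list(pairs, mirna_ref, config.species, viab)
        write_count_table(annotated, ws.path("mirna_list_annotated.tsv"))

        stage = "stats-list"
        up = annotated.loc[annotated["weight"] > 0].copy()
        down = annotated.loc[annotated["weight"] < 0].copy()
        down["weight"] = -down["weight"]
        tables = {name: t for name, t in (("up", up), ("down", down)) if len(t)}
        weights = {name: "weight" for name in tables}
        ecfg = ExpansionConfig(divisor=config.divisor)
        block = _stats_block(ws, tables, weights, "mirna_list", ecfg, config.bin_width)

        stage = "manifest"
        manifest = {
            "seedviab_version": __version__,
            "config": config.to_dict(),
            "mode": "mirna-list",
            "inputs": {
                "list_csv": _sha256(csv_path),
                "viability_csv": _sha256(config.viability_csv),
                "reference:miRNA": _sha256(mirna_path),
            },
        }
        with open(ws.path("manifest.json"), "w") as handle:
            json.dump(manifest, handle, indent=2, sort_keys=True)
            handle.write("\n")
    except Exception as exc:
        ws.discard()
        raise SeedViabError(f"stage {stage!r} failed: {exc}") from exc
    return {"outdir": ws.outdir, "annotated": annotated, "stats": block,
            "manifest": manifest}
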
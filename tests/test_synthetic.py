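import numpy as np
import pandas as pd
import pytest

from seedviab import (
    ConfigError,
    annotate_table,
    extract_seed,
    filter_rare,
    gen_counts,
    gen_fastq,
    gen_references,
    gen_viability_table,
)
from seedviab.preprocess import fastq_to_counts
from seedviab.synthetic import SimulationConfig


def small_cfg(**kw):
    defaults = dict(rng_seed=5, n_rows=60, samples_per_group=2, depth=3000.0)
    defaults.update(kw)
    return SimulationConfig(**defaults)


def test_viability_table_is_complete_and_toxicity_structured(viab):
    assert len(viab) == 4096
    avg = viab.species_average("human")
    assert avg["GGGGGG"] < avg["AAAAAA"]
    # G-weighted monotone structure holds on species averages (noise << slope)
    assert avg["GGGGGG"] < avg["CCCCCC"] < avg["AAAAAA"]


def test_viability_table_generation_is_deterministic(tmp_path):
    a, b = tmp_path / "a.csv", tmp_path / "b.csv"
    gen_viability_table(123).to_csv(a)
    gen_viability_table(123).to_csv(b)
    assert a.read_bytes() == b.read_bytes()


def test_simulation_config_validation():
    with pytest.raises(ConfigError, match="samples_per_group"):
        SimulationConfig(samples_per_group=1)
    with pytest.raises(ConfigError, match="fractions"):
        SimulationConfig(fraction_mirna=0.9, fraction_rnaworld=0.3)
    with pytest.raises(ConfigError, match="shift"):
        SimulationConfig(shift=1.5)


def test_gen_counts_ground_truth_is_consistent(viab):
    cfg = small_cfg()
    raw, truth = gen_counts(cfg, viab)
    assert list(raw.index) == list(truth.frame.index)
    assert raw.shape == (cfg.n_rows, 2 * cfg.samples_per_group)
    avg = viab.species_average(cfg.species)
    for seq, row in truth.frame.iterrows():
        assert extract_seed(seq) == row["seed"]
        assert row["viability"] == pytest.approx(avg[row["seed"]])


def test_gen_counts_is_deterministic(viab):
    a, _ = gen_counts(small_cfg(), viab)
    b, _ = gen_counts(small_cfg(), viab)
    pd.testing.assert_frame_equal(a, b)


def test_references_match_planted_annotations_exactly(viab):
    cfg = small_cfg(n_rows=120, fraction_artificial=0.15)
    raw, truth = gen_counts(cfg, viab)
    refs = gen_references(truth, cfg.rng_seed)

    for name, seq in refs["miRNA"].records:
        assert seq in truth.frame.index  # simulated miRNA rows verbatim

    planted = set(truth.frame.index[truth.frame["rna_type"] == "artificial"])
    ann = annotate_table(raw, list(refs.values()), cfg.species, viab)
    removed = set(raw.index) - set(ann.index)
    assert removed == planted

    # surviving annotations equal the planted ground truth
    surviving = truth.frame.loc[ann.index]
    assert (ann["rna_type"] == surviving["rna_type"]).all()

    for _, mi_seq in refs["miRNA"].records:
        for _, art_seq in refs["artificial"].records:
            assert mi_seq not in art_seq


def test_fastq_round_trips_through_preprocessing(tmp_path, viab):
    cfg = small_cfg(n_rows=80)
    raw, _ = gen_counts(cfg, viab)
    paths = gen_fastq(raw, cfg.adapter, cfg.rng_seed, tmp_path)
    rebuilt, _ = fastq_to_counts(paths, cfg.adapter, min_total=6)
    pd.testing.assert_frame_equal(rebuilt, filter_rare(raw, 6))


def test_fastq_record_counts_equal_column_sums(tmp_path, viab):
    cfg = small_cfg(n_rows=20, depth=300.0)
    raw, _ = gen_counts(cfg, viab)
    paths = gen_fastq(raw, cfg.adapter, 0, tmp_path)
    for sample, path in paths.items():
        n_records = sum(1 for line in open(path) if line.startswith("@"))
        assert n_records == raw[sample].sum()


def test_fastq_of_empty_table_is_valid_and_empty(tmp_path):
    empty = pd.DataFrame({"s1": [], "s2": []}, index=pd.Index([], name="sequence"))
    paths = gen_fastq(empty, "UGGAAUUCUCGGGUGCCAAGG", 0, tmp_path)
    for path in paths.values():
        assert path.exists() and path.read_text() == ""


def test_shift_depresses_perturbed_viability(viab):
    from seedviab import expand, normalize_counts

    cfg = small_cfg(n_rows=200, depth=5e4, samples_per_group=3, shift=0.8)
    raw, truth = gen_counts(cfg, viab)
    assert truth.expected_median_sign == -1
    ann = annotate_table(raw, [], cfg.species, viab)
    norm = normalize_counts(ann)
    groups = cfg.sample_groups()
    medians = {}
    for name, samples in groups.items():
        table = norm.copy()
        table["mean"] = norm[samples].mean(axis=1)
        medians[name] = expand(table, "mean").median()
    assert medians["perturbed"] < medians["control"]
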
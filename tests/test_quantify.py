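"""Expression quantification: counts, multi-read distribution, TPM,
saturation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from scipy.stats import pearsonr

from tagdge.preprocess import TagLibrary
from tagdge.quantify import (
    ExpressionMatrix,
    distribute_multireads,
    gene_counts,
    saturation_curve,
    tpm,
)
from tagdge.refdb import ReferenceTagDB
from tagdge.simulate import SimulationConfig, simulate_dataset
from tagdge.tagmap import MappingResult, TagAssignment, map_library

from conftest import random_seq


def make_mapping(entries):
    """entries: (tag, count, status, genes)"""
    m = MappingResult(label="x")
    for tag, count, status, genes in entries:
        dist = None if status == "unknown" else 0
        m.assignments[tag] = TagAssignment(status, frozenset(genes), dist)
        m.counts[tag] = count
    return m


def test_gene_counts_sums_unambiguous_tags():
    m = make_mapping([
        ("T1", 30, "unambiguous", {"g"}),
        ("T2", 12, "unambiguous", {"g"}),
        ("T3", 99, "ambiguous", {"g", "h"}),
        ("T4", 5, "unknown", set()),
    ])
    counts = gene_counts(m)
    assert counts["g"] == 42
    assert "h" not in counts  # only ambiguous evidence -> raw count 0


def test_multiread_proportional_split():
    m = make_mapping([("T", 10, "ambiguous", {"g", "h"})])
    counts = pd.Series({"g": 30.0, "h": 10.0})
    dist, discarded = distribute_multireads(m, counts)
    assert dist["g"] == pytest.approx(37.5)
    assert dist["h"] == pytest.approx(12.5)
    assert discarded == 0


def test_multiread_equal_split_without_unique_evidence():
    m = make_mapping([("T", 10, "ambiguous", {"g", "h"})])
    dist, _ = distribute_multireads(m, pd.Series(dtype=float))
    assert dist["g"] == pytest.approx(5.0) and dist["h"] == pytest.approx(5.0)


def test_multiread_cap_discards_wide_tags():
    genes = {f"g{i}" for i in range(25)}
    m = make_mapping([("T", 10, "ambiguous", genes)])
    dist, discarded = distribute_multireads(m, pd.Series(dtype=float), cap=20)
    assert discarded == 10 and dist.sum() == 0


def test_multiread_random_instances_match_enumeration_oracle():
    rng = np.random.default_rng(23)
    genes = [f"g{i}" for i in range(30)]
    for _ in range(20):
        counts = pd.Series(rng.integers(0, 50, size=30).astype(float),
                           index=genes)
        entries = []
        for t in range(50):
            size = int(rng.integers(2, 25))
            members = set(rng.choice(genes, size=size, replace=False))
            entries.append((f"T{t}", int(rng.integers(1, 30)), "ambiguous",
                            members))
        m = make_mapping(entries)
        dist, discarded = distribute_multireads(m, counts, cap=20)
        # oracle: apply the rule tag by tag
        expected = counts.copy()
        expected_discarded = 0.0
        for tag, count, _, members in entries:
            members = sorted(members)
            if len(members) > 20:
                expected_discarded += count
                continue
            w = np.array([counts[g] for g in members])
            if w.sum() == 0:
                w = np.ones(len(members))
            for g, share in zip(members, count * w / w.sum()):
                expected[g] += share
        assert discarded == expected_discarded
        pd.testing.assert_series_equal(dist, expected.sort_index())
        total_in = counts.sum() + sum(e[1] for e in entries)
        assert dist.sum() + discarded == pytest.approx(total_in)


@pytest.mark.parametrize(
    "count,total,expected",
    [(0, 100, 0.0), (3_500_000, 3_500_000, 1e6), (70, 3_500_000, 20.0)],
)
def test_tpm_arithmetic(count, total, expected):
    assert tpm(pd.Series([float(count)]), total).iloc[0] == pytest.approx(expected)


def test_tpm_zero_denominator_rejected():
    with pytest.raises(ValueError):
        tpm(pd.Series([1.0]), 0)


def test_matrix_mass_conservation(small_dataset):
    config, _, _, libraries, db = small_dataset
    from tagdge.preprocess import filter_raw_tags

    clean = {
        s: filter_raw_tags(lib, (config.adaptor_prefix,))
        for s, lib in list(libraries.items())[:2]
    }
    mappings = {s: map_library(lib, db) for s, lib in clean.items()}
    matrix = ExpressionMatrix.from_mappings(mappings, genes=db.gene_ids)
    for s, m in mappings.items():
        mapped_mass = m.unambiguous_tag_total + m.ambiguous_tag_total
        assert matrix.distributed[s].sum() + matrix.discarded[s] == pytest.approx(
            mapped_mass
        )
        # sum of TPM never exceeds one million
        assert matrix.tpm[s].sum() <= 1e6 + 1e-6


def test_tpm_recovers_true_abundance_on_clean_simulation():
    config = SimulationConfig(
        n_genes=100, library_depth=100_000, base_error_rate=0.0,
        adaptor_fraction=0.0, n_fraction=0.0, singleton_fraction=0.0,
        offref_fraction=0.0, taggable_fraction=1.0, seed=29,
    )
    _, truth, libraries, db = simulate_dataset(config)
    mappings = {s: map_library(lib, db) for s, lib in libraries.items()}
    matrix = ExpressionMatrix.from_mappings(mappings, genes=db.gene_ids)
    for s in ("0h", "EC"):
        r, _ = pearsonr(matrix.tpm[s], 1e6 * truth.abundance[s])
        assert r >= 0.99


def test_tpm_converges_to_scaled_abundance_at_high_depth():
    """With no error or contamination, TPM approaches 1e6 x true
    abundance; at a million tags over 100 equally expressed genes the
    worst relative error stays below 5%."""
    config = SimulationConfig(
        n_genes=100, library_depth=1_000_000, base_error_rate=0.0,
        adaptor_fraction=0.0, n_fraction=0.0, singleton_fraction=0.0,
        offref_fraction=0.0, taggable_fraction=1.0,
        abundance_log2_sd=0.0, template_jitter_sd=0.0,
        archetype_mix={"flat": 1.0}, stages=("0h",), seed=31,
    )
    _, truth, libraries, db = simulate_dataset(config)
    mapping = map_library(libraries["0h"], db)
    matrix = ExpressionMatrix.from_mappings({"0h": mapping}, genes=db.gene_ids)
    expected = 1e6 * truth.abundance["0h"]
    rel_err = ((matrix.tpm["0h"] - expected) / expected).abs()
    assert rel_err.max() <= 0.05


class TestSaturation:
    def _library(self, db, genes, count=10):
        return TagLibrary("x", {db.canonical_tag(g): count for g in genes})

    def test_full_fraction_equals_full_library(self, toy_db):
        lib = self._library(toy_db, ("gA", "gB", "gC"))
        table = saturation_curve(lib, toy_db, [0.5, 1.0], reps=2, seed=0)
        full = table.loc[table["fraction"] == 1.0, "genes_detected"].iloc[0]
        assert full == 3

    def test_detected_counts_monotone_in_fraction(self, small_dataset):
        config, _, _, libraries, db = small_dataset
        from tagdge.preprocess import filter_raw_tags

        clean = filter_raw_tags(libraries["6h"], (config.adaptor_prefix,))
        table = saturation_curve(clean, db, [i / 10 for i in range(1, 11)],
                                 reps=2, seed=1)
        assert (np.diff(table["genes_detected"]) >= 0).all()

    def test_mean_detected_matches_hypergeometric_expectation(self):
        genes = [(f"g{i}", "CATG" + random_seq(np.random.default_rng(i), 17))
                 for i in range(10)]
        db = ReferenceTagDB.from_records(genes)
        lib = self._library(db, [g for g, _ in genes], count=10)
        total, m = 100, 50
        expected = sum(
            1 - comb(total - 10, m, exact=True) / comb(total, m, exact=True)
            for _ in range(10)
        )
        table = saturation_curve(lib, db, [0.5], reps=3000, seed=2)
        observed = table["genes_detected"].iloc[0]
        assert observed == pytest.approx(expected, abs=0.05)
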
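"""Fragmentation: size models, G+C computation, and reference shearing."""

import numpy as np
import pytest

from sipreads.exceptions import ConfigurationError, DomainError, InputError
from sipreads.fragments import (
    Fragment,
    FragmentSizeModel,
    Reference,
    fragment_reference,
    fragments_to_table,
    gc_content,
)
from sipreads.synthetic import SyntheticGenomeSpec, make_genome


def _reference(length=100_000, gc=0.5, seed=3, n_scaffolds=1):
    scaffolds = {}
    per = length // n_scaffolds
    for i in range(n_scaffolds):
        rec = make_genome(
            SyntheticGenomeSpec(length=per, gc=gc, drift_amplitude=0.0, seed=seed + i)
        )
        scaffolds[f"scf_{i + 1}"] = str(rec.seq)
    return Reference(id="ref_a", scaffolds=scaffolds)


class TestGCContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATGC", 0.5), ("AAAA", 0.0), ("ATGN", 1.0 / 3.0), ("atgc", 0.5)],
    )
    def test_examples(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    @pytest.mark.parametrize("seq", ["", "NNNN"])
    def test_undefined_windows_rejected(self, seq):
        with pytest.raises(DomainError):
            gc_content(seq)


class TestFragmentSizeModel:
    def test_degenerate_uniform_is_constant(self, rng):
        model = FragmentSizeModel(family="uniform", location=5000, scale=5000)
        assert np.all(model.sample(100, rng) == 5000)

    def test_normal_mean_within_two_se(self, rng):
        model = FragmentSizeModel(family="normal", location=9000, scale=2500)
        draws = model.sample(10_000, rng)
        se = 2500 / np.sqrt(10_000)
        assert abs(draws.mean() - 9000) < 3 * se + 0.5  # +0.5 for integer rounding

    @pytest.mark.parametrize("family", ["truncated-normal", "skew-normal"])
    def test_truncation_respected(self, family, rng):
        model = FragmentSizeModel(
            family=family, location=5000, scale=3000, skew=4.0, min_bp=2000, max_bp=8000
        )
        draws = model.sample(5000, rng)
        assert draws.min() >= 2000 and draws.max() <= 8000

    def test_skew_shifts_mean(self, rng):
        right = FragmentSizeModel(family="skew-normal", location=5000, scale=2000, skew=8.0)
        assert right.mean > 5000

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"family": "exponential"},
            {"family": "normal", "scale": 0},
            {"family": "uniform", "location": 9000, "scale": 5000},
            {"min_bp": 0},
        ],
    )
    def test_invalid_models_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            FragmentSizeModel(**kwargs)


class TestFragmentReference:
    def test_degenerate_tiling_reaches_exact_coverage(self):
        """100 kb at coverage 2 with fixed 5 kb tiles: two full passes.

        Every pass covers the scaffold exactly once, so summed bases are
        exactly 200 kb; up to two boundary fragments per pass may differ
        from 5 kb because of the random tiling phase.
        """
        ref = _reference(length=100_000)
        model = FragmentSizeModel(family="uniform", location=5000, scale=5000)
        frags = fragment_reference(ref, model, coverage=2.0, rng=np.random.default_rng(5))
        total = sum(f.length for f in frags)
        assert total == 200_000
        assert 40 <= len(frags) <= 44
        assert sum(1 for f in frags if f.length == 5000) >= len(frags) - 4

    def test_coverage_bound(self):
        ref = _reference(length=50_000)
        model = FragmentSizeModel(family="normal", location=4000, scale=800, min_bp=500, max_bp=8000)
        for coverage in (0.5, 1.0, 2.5):
            frags = fragment_reference(ref, model, coverage, rng=np.random.default_rng(11))
            realized = sum(f.length for f in frags) / ref.total_length
            assert coverage <= realized <= coverage + (model.max_bp + model.min_bp) / ref.total_length

    def test_coordinates_extract_exactly(self):
        ref = _reference(length=30_000)
        model = FragmentSizeModel(family="normal", location=2000, scale=300, min_bp=500)
        frags = fragment_reference(ref, model, 1.0, rng=np.random.default_rng(2))
        for f in frags:
            seq = ref.scaffolds[f.scaffold_id]
            assert 0 <= f.start < f.end <= len(seq)
            window = f.sequence(seq)
            assert len(window) == f.length
            assert gc_content(window) == pytest.approx(f.gc)

    def test_fragments_never_span_scaffolds(self):
        ref = _reference(length=40_000, n_scaffolds=4)
        model = FragmentSizeModel(family="normal", location=3000, scale=500, min_bp=500)
        frags = fragment_reference(ref, model, 1.5, rng=np.random.default_rng(8))
        for f in frags:
            assert f.end <= len(ref.scaffolds[f.scaffold_id])
        assert {f.scaffold_id for f in frags} == set(ref.scaffolds)

    def test_bit_reproducible_under_seed(self):
        ref = _reference()
        model = FragmentSizeModel()
        a = fragment_reference(ref, model, 1.0, rng=np.random.default_rng(42))
        b = fragment_reference(ref, model, 1.0, rng=np.random.default_rng(42))
        assert [(f.start, f.end, f.scaffold_id) for f in a] == [
            (f.start, f.end, f.scaffold_id) for f in b
        ]

    def test_fragment_gc_converges_to_genome_gc(self):
        ref = _reference(length=200_000, gc=0.42, seed=9)
        model = FragmentSizeModel(family="normal", location=5000, scale=1000, min_bp=1000)
        frags = fragment_reference(ref, model, 2.0, rng=np.random.default_rng(1))
        weights = np.array([f.length for f in frags], dtype=float)
        mean_gc = np.average([f.gc for f in frags], weights=weights)
        # binomial SE of the whole-genome G+C estimate
        se = np.sqrt(0.42 * 0.58 / ref.total_length)
        assert abs(mean_gc - 0.42) < 3 * se + 0.005

    def test_short_scaffold_fallback(self, caplog):
        ref = Reference(id="tiny", scaffolds={"s1": "ACGT" * 100})
        model = FragmentSizeModel(family="normal", location=2000, scale=100, min_bp=1000)
        with caplog.at_level("WARNING"):
            frags = fragment_reference(ref, model, 1.0, rng=np.random.default_rng(0))
        assert len(frags) == 1 and frags[0].length == 400

    def test_empty_reference_rejected(self):
        with pytest.raises(InputError):
            fragment_reference(
                Reference(id="x", scaffolds={}),
                FragmentSizeModel(),
                1.0,
                rng=np.random.default_rng(0),
            )

    def test_invalid_coverage_rejected(self):
        with pytest.raises(ConfigurationError):
            fragment_reference(_reference(), FragmentSizeModel(), 0.0, rng=1)


def test_fasta_round_trip(tmp_path):
    from sipreads.synthetic import write_genome_fasta

    rec = make_genome(SyntheticGenomeSpec(length=5000, gc=0.5, seed=1, name="g1"))
    path = tmp_path / "g1.fasta"
    write_genome_fasta(rec, path)
    ref = Reference.from_fasta(path)
    assert ref.id == "g1"
    assert ref.scaffolds["g1"] == str(rec.seq)


def test_fragment_table_columns():
    frags = [Fragment("r", "s", 0, 100, 0.5)]
    table = fragments_to_table(frags)
    assert list(table.columns) == ["reference_id", "scaffold_id", "start", "end", "length", "gc"]
    assert table.loc[0, "length"] == 100
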
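"""Synthetic reference and read simulation: determinism, weights, truth, FASTQ."""

import numpy as np
import pytest

from hlbscreen.annotation import build_default_annotation
from hlbscreen.simulate import (
    FLANK,
    GA_SYNTHETIC,
    ReadSet,
    SimConfig,
    SimMode,
    build_reference,
    position_weights,
    read_fastq,
    simulate_pair,
    write_fastq,
)


def small_config(**kw):
    base = dict(n_copies=3, flank_length=1000, n_reads_chip=2000,
                n_reads_input=2000, seed=11)
    base.update(kw)
    return SimConfig(**base)


class TestBuildReference:
    def test_total_length(self, annotation):
        ref, offsets = build_reference(annotation, n_copies=3, flank_length=1000, seed=1)
        assert len(ref) == 3 * 5000 + 2 * 1000
        assert offsets == [1000, 6000, 11000]

    def test_deterministic(self, annotation):
        a, _ = build_reference(annotation, 2, 500, seed=42)
        b, _ = build_reference(annotation, 2, 500, seed=42)
        assert a == b
        c, _ = build_reference(annotation, 2, 500, seed=43)
        assert a != c

    def test_copies_identical(self, annotation, small_reference):
        ref, offsets = small_reference
        units = [ref[o : o + 5000] for o in offsets]
        assert units[0] == units[1] == units[2]

    def test_ga_features_are_perfect_repeats(self, annotation, small_reference):
        ref, offsets = small_reference
        unit = ref[offsets[0] : offsets[0] + 5000]
        for f in build_default_annotation().by_kind("ga_repeat"):
            sub = unit[f.start : f.end]
            assert sub == "GA" * (f.length // 2)


class TestPositionWeights:
    def test_none_is_uniform(self, annotation):
        w = position_weights(annotation, SimMode.NONE, small_config())
        assert np.allclose(w, 1 / 5000)

    def test_true_promoter_fold_ratio(self, annotation):
        cfg = small_config(mode=SimMode.TRUE_PROMOTER, enrichment_fold=8.0)
        w = position_weights(annotation, SimMode.TRUE_PROMOTER, cfg, role="chip")
        t = annotation.feature("H3_H4_promoter")
        on = w[t.start]
        off = w[0]
        assert on / off == pytest.approx(8.0)
        w_in = position_weights(annotation, SimMode.TRUE_PROMOTER, cfg, role="input")
        assert np.allclose(w_in, 1 / 5000)

    def test_input_identical_enriches_both_roles(self, annotation):
        cfg = small_config(mode=SimMode.INPUT_IDENTICAL, enrichment_fold=8.0)
        wc = position_weights(annotation, SimMode.INPUT_IDENTICAL, cfg, role="chip")
        wi = position_weights(annotation, SimMode.INPUT_IDENTICAL, cfg, role="input")
        assert np.array_equal(wc, wi)
        assert wc.max() > wc.min()

    @pytest.mark.parametrize("mode", list(SimMode))
    def test_normalized(self, annotation, mode):
        cfg = small_config(mode=mode, bias_weight=0.2 if mode is SimMode.INTERGENIC_DEPLETION else 3.0)
        for role in ("chip", "input"):
            w = position_weights(annotation, mode, cfg, role)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert (w >= 0).all()

    def test_nonpositive_bias_rejected(self):
        with pytest.raises(ValueError):
            small_config(bias_weight=0.0)


class TestSimulatePair:
    def test_deterministic_fastq_bytes(self, annotation, small_reference, tmp_path):
        ref, _ = small_reference
        cfg = small_config()
        files = []
        for run in (1, 2):
            chip, _ = simulate_pair(ref, annotation, cfg)
            p = tmp_path / f"chip{run}.fastq"
            write_fastq(chip, p)
            files.append(p.read_bytes())
        assert files[0] == files[1]

    def test_uniform_window_fraction_binomial(self, annotation, small_reference):
        """Under NONE, ~10% of reads start in a 500 bp window (3 binomial SD)."""
        ref, _ = small_reference
        cfg = small_config(mode=SimMode.NONE, n_reads_input=10_000)
        _, inp = simulate_pair(ref, annotation, cfg)
        offs = inp.truth_offset[inp.truth_kind == ReadSet.TRUTH_ARRAY]
        p = 500 / 5000
        frac = ((offs >= 1000) & (offs < 1500)).mean()
        sd = np.sqrt(p * (1 - p) / len(offs))
        assert abs(frac - p) < 3 * sd

    def test_ga_artifact_read_count_exact(self, annotation, small_reference):
        ref, _ = small_reference
        cfg = small_config(mode=SimMode.GA_ARTIFACT, n_reads_chip=20_000,
                           artifact_read_fraction=0.05, read_length=36)
        chip, inp = simulate_pair(ref, annotation, cfg)
        assert int((chip.truth_kind == ReadSet.TRUTH_GA).sum()) == 1000
        assert int((inp.truth_kind == ReadSet.TRUTH_GA).sum()) == 0

    def test_enrichment_fold_converges(self, annotation, small_reference):
        """On/off element read-start density ratio approaches the configured fold."""
        ref, _ = small_reference
        cfg = small_config(mode=SimMode.TRUE_PROMOTER, n_reads_chip=200_000,
                           enrichment_fold=8.0)
        chip, _ = simulate_pair(ref, annotation, cfg)
        t = annotation.feature("H3_H4_promoter")
        offs = chip.truth_offset[chip.truth_kind == ReadSet.TRUTH_ARRAY]
        on = ((offs >= t.start) & (offs < t.end)).sum() / t.length
        off = ((offs < t.start) | (offs >= t.end)).sum() / (5000 - t.length)
        assert on / off == pytest.approx(8.0, rel=0.10)

    def test_interior_copy_reads_match_reference_slice(self, annotation, small_reference):
        """Array-origin reads equal the literal reference substring for
        interior copies (collapse is on identical copies, not fiction)."""
        from hlbscreen.dna import decode

        ref, offsets = small_reference
        cfg = small_config(n_reads_chip=500, read_length=50)
        chip, _ = simulate_pair(ref, annotation, cfg)
        checked = 0
        for i in range(len(chip)):
            if chip.truth_kind[i] != ReadSet.TRUTH_ARRAY:
                continue
            copy, off = int(chip.truth_copy[i]), int(chip.truth_offset[i])
            if copy >= 2:  # last copy may wrap into the (identical) next unit
                continue
            start = offsets[copy] + off
            expected = ref[start : start + 50]
            seq = decode(chip.seqs[i])
            from hlbscreen.dna import revcomp

            assert seq in (expected, revcomp(expected))
            checked += 1
        assert checked > 100

    def test_truth_partition(self, annotation, small_reference):
        """Every read has exactly one truth origin."""
        ref, _ = small_reference
        cfg = small_config(mode=SimMode.GA_ARTIFACT, read_length=36,
                           flank_read_fraction=0.02)
        chip, _ = simulate_pair(ref, annotation, cfg)
        kinds = {FLANK: 0, GA_SYNTHETIC: 0, "array": 0}
        for read in chip:
            t = read.truth_origin
            if t == FLANK:
                kinds[FLANK] += 1
            elif t == GA_SYNTHETIC:
                kinds[GA_SYNTHETIC] += 1
            else:
                assert isinstance(t, tuple) and len(t) == 2
                kinds["array"] += 1
        assert sum(kinds.values()) == len(chip)
        assert kinds[FLANK] > 0 and kinds[GA_SYNTHETIC] > 0

    def test_read_length_exceeding_unit_rejected(self, annotation):
        with pytest.raises(ValueError, match="read_length"):
            ref, _ = build_reference(build_default_annotation(), 1, 100, seed=0)
            simulate_pair(ref, annotation, SimConfig(n_copies=1, flank_length=100,
                                                     read_length=5001))


class TestFastqRoundTrip:
    def test_identity_on_100_reads(self, annotation, small_reference, tmp_path):
        ref, _ = small_reference
        cfg = small_config(n_reads_chip=100, mode=SimMode.GA_ARTIFACT,
                           read_length=36, flank_read_fraction=0.05)
        chip, _ = simulate_pair(ref, annotation, cfg)
        p = tmp_path / "x.fastq"
        write_fastq(chip, p)
        back = read_fastq(p, role="chip")
        assert back.ids == chip.ids
        assert np.array_equal(back.seqs, chip.seqs)
        assert np.array_equal(back.truth_kind, chip.truth_kind)
        assert np.array_equal(back.truth_copy, chip.truth_copy)
        assert np.array_equal(back.truth_offset, chip.truth_offset)

    def test_empty_set_round_trips(self, tmp_path):
        empty = ReadSet("chip", [], np.empty((0, 0), dtype=np.uint8),
                        np.empty(0, dtype=np.int8), np.empty(0, dtype=np.int64),
                        np.empty(0, dtype=np.int64))
        p = tmp_path / "empty.fastq"
        write_fastq(empty, p)
        assert p.read_text() == ""
        assert len(read_fastq(p)) == 0

    def test_seq_qual_length_mismatch_names_record(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r0\nACGT\n+\nIII\n")
        with pytest.raises(ValueError, match="record 0"):
            read_fastq(p)
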
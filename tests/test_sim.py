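"""The shattering-and-inheritance simulator against first-principles oracles."""

import itertools
import json
from dataclasses import replace

import numpy as np
import pytest

from chromobal import (
    Fragment,
    SimConfig,
    assign_fragments,
    derive_cn_profile,
    derive_junctions,
    partition_ratio,
    reassemble_and_derive_svs,
    read_bedpe_svs,
    read_cn_segments,
    shatter,
    simulate_sample,
)
from chromobal.sim import write_sample

from conftest import enumerate_derivatives, string_reconstruction_classes

MB = 1_000_000


def frags(*bounds, fate="daughterA"):
    return [Fragment(a, b, fate=fate) for a, b in zip(bounds, bounds[1:])]


class TestShatter:
    def test_no_breakpoints_single_fragment(self):
        cfg = SimConfig(n_breakpoints=0)
        (frag,) = shatter(cfg, np.random.default_rng(0))
        assert (frag.ref_start, frag.ref_end) == cfg.shatter_region

    def test_fragments_tile_region(self):
        cfg = SimConfig(n_breakpoints=3)
        out = shatter(cfg, np.random.default_rng(5))
        assert len(out) == 4
        assert sum(f.length for f in out) == cfg.shatter_region[1] - cfg.shatter_region[0]
        for a, b in zip(out, out[1:]):
            assert a.ref_end == b.ref_start

    def test_seed_determinism(self):
        cfg = SimConfig(n_breakpoints=12)
        assert shatter(cfg, np.random.default_rng(9)) == shatter(
            cfg, np.random.default_rng(9)
        )

    def test_too_many_breakpoints(self):
        cfg = SimConfig(chrom_length=1_000, shatter_region=(0, 10), n_breakpoints=10)
        with pytest.raises(ValueError, match="breakpoints"):
            shatter(cfg, np.random.default_rng(0))


class TestAssign:
    def test_clustered_all_daughter_a(self):
        out = assign_fragments(frags(0, 10, 20, 30), "clustered", 0.0,
                               np.random.default_rng(0))
        assert all(f.fate == "daughterA" for f in out)

    def test_full_loss(self):
        out = assign_fragments(frags(0, 10, 20), "dispersed", 1.0,
                               np.random.default_rng(0))
        assert all(f.fate == "cytoplasm" for f in out)

    def test_dispersed_split_near_half(self):
        # binomial 99% interval at n=10,000: 0.5 +/- 0.015
        fragments = frags(*range(0, 10_001))
        out = assign_fragments(fragments, "dispersed", 0.0, np.random.default_rng(42))
        frac_a = sum(f.fate == "daughterA" for f in out) / len(out)
        assert abs(frac_a - 0.5) < 0.015


class TestReassembly:
    def test_identity_no_flips_yields_no_junctions(self):
        derivative = frags(0, 10, 20, 30)  # reference order, all forward
        assert derive_junctions(derivative) == []

    def test_reordered_fragments_del_dup(self):
        a, b, c = frags(0, 10, 20, 30)
        svs = derive_junctions([a, c, b], chrom="chrT")
        assert [sv.sv_class for sv in svs] == ["DEL", "DUP"]

    def test_middle_inversion_h2h_t2t(self):
        a, b, c = frags(0, 10, 20, 30)
        svs = derive_junctions([a, replace(b, orientation="reverse"), c], chrom="chrT")
        assert [sv.sv_class for sv in svs] == ["h2hINV", "t2tINV"]

    def test_reverse_adjacent_pair_suppressed(self):
        a, b = frags(0, 10, 20)
        ra, rb = replace(a, orientation="reverse"), replace(b, orientation="reverse")
        assert derive_junctions([rb, ra]) == []

    @pytest.mark.parametrize("n_fragments", [2, 3, 4, 5])
    def test_matches_string_oracle_exhaustively(self, n_fragments):
        # all derivatives of <= 5 fragments on a <= 50 bp toy reference,
        # including a 1 bp fragment (orientation matters via the complement)
        cuts = {2: (21,), 3: (9, 30), 4: (7, 19, 28), 5: (7, 8, 19, 33)}[n_fragments]
        bounds = (0, *cuts, 42)
        fragments = frags(*bounds)
        for derivative in enumerate_derivatives(fragments):
            got = [sv.sv_class for sv in derive_junctions(derivative, chrom="chrT")]
            expected = string_reconstruction_classes(derivative, 42)
            assert got == expected, derivative

    def test_junction_count_identity(self):
        # emitted SVs = adjacencies - reference-adjacent co-oriented pairs
        fragments = frags(0, 5, 11, 20, 27)
        for derivative in enumerate_derivatives(fragments):
            suppressed = 0
            for left, right in zip(derivative, derivative[1:]):
                same = left.orientation == right.orientation
                if same and left.orientation == "forward":
                    suppressed += left.ref_end == right.ref_start
                elif same:
                    suppressed += left.ref_start == right.ref_end
            svs = derive_junctions(derivative)
            assert len(svs) == len(derivative) - 1 - suppressed

    def test_anchor_first_fragment(self):
        fragments = frags(0, 10, 20, 30, 40)
        derivative, _ = reassemble_and_derive_svs(
            fragments, np.random.default_rng(1), anchor_first=True
        )
        assert derivative[0].ref_start == 0
        assert derivative[0].orientation == "forward"

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            reassemble_and_derive_svs([], np.random.default_rng(0))


class TestCnProfile:
    def test_all_retained_flat(self):
        cfg = SimConfig(background_ploidy=1)
        start, end = cfg.shatter_region
        fragments = frags(start, (start + end) // 2, end)
        (seg,) = derive_cn_profile(fragments, cfg)
        assert (seg.start, seg.end, seg.total_cn) == (0, cfg.chrom_length, 1)

    def test_middle_loss_oscillates(self):
        cfg = SimConfig(background_ploidy=1)
        start, end = cfg.shatter_region
        a, b, c = frags(start, start + MB, start + 2 * MB, end)
        fragments = [a, replace(b, fate="cytoplasm"), c]
        cns = [s.total_cn for s in derive_cn_profile(fragments, cfg)]
        assert cns == [1, 0, 1]

    def test_retained_length_conservation(self):
        cfg = SimConfig(n_breakpoints=20, p_loss=0.4, mode="dispersed", seed=7)
        sample = simulate_sample(cfg)
        region = cfg.shatter_region[1] - cfg.shatter_region[0]
        retained = sum(f.length for f in sample.fragments if f.fate == "daughterA")
        inside = sum(
            (min(s.end, cfg.shatter_region[1]) - max(s.start, cfg.shatter_region[0]))
            * (s.total_cn - cfg.background_ploidy + 1)
            for s in sample.cn
            if s.end > cfg.shatter_region[0] and s.start < cfg.shatter_region[1]
        )
        assert inside == retained
        assert sample.loss_fraction == pytest.approx((region - retained) / region)


class TestPartitionRatio:
    def test_clustered_is_zero_to_one(self):
        assert partition_ratio(frags(0, 10, 25, 40)) == 0.0

    def test_even_split_is_one(self):
        a, b = frags(0, 10, 20)
        assert partition_ratio([a, replace(b, fate="daughterB")]) == 1.0

    def test_enumeration_four_equal_fragments(self):
        # mean of min/max over all 16 equiprobable fates = 13/24
        fragments = frags(0, 10, 20, 30, 40)
        ratios = []
        for fates in itertools.product(("daughterA", "daughterB"), repeat=4):
            assigned = [replace(f, fate=fate) for f, fate in zip(fragments, fates)]
            ratios.append(partition_ratio(assigned))
        assert sum(ratios) / 16 == pytest.approx(13 / 24)

    def test_all_cytoplasm_error(self):
        with pytest.raises(ValueError):
            partition_ratio(frags(0, 10, fate="cytoplasm"))


class TestSimulateSample:
    def test_clustered_lossless_truth(self):
        sample = simulate_sample(SimConfig(mode="clustered", seed=11))
        assert sample.truth_label == "balanced"
        assert sample.loss_fraction == 0.0
        assert sample.partition_ratio == 0.0
        cns = {s.total_cn for s in sample.cn}
        assert cns == {1}  # flat profile

    def test_dispersed_truth_canonical(self):
        sample = simulate_sample(SimConfig(mode="dispersed", seed=11))
        assert sample.truth_label == "canonical"
        assert 0 < sample.loss_fraction < 1

    def test_chromoplexy_chain(self):
        sample = simulate_sample(SimConfig(mode="chromoplexy", seed=11))
        assert sample.truth_label == "chromoplexy"
        assert [sv.sv_class for sv in sample.svs] == ["TRA", "TRA", "TRA"]
        chroms = {s.chrom: s.total_cn for s in sample.cn}
        assert len({(s.chrom, s.total_cn) for s in sample.cn}) == len(chroms)  # flat

    def test_same_seed_bit_identical(self, tmp_path):
        cfg = SimConfig(mode="dispersed", n_breakpoints=15, p_loss=0.1, seed=23)
        s1 = simulate_sample(cfg, "a")
        s2 = simulate_sample(cfg, "a")
        assert s1.svs == s2.svs and s1.cn == s2.cn
        write_sample(s1, tmp_path / "r1")
        write_sample(s2, tmp_path / "r2")
        for name in ("a.bedpe", "a.cn.tsv", "a.truth.json"):
            assert (tmp_path / "r1" / name).read_text() == (
                tmp_path / "r2" / name
            ).read_text()

    def test_written_files_round_trip(self, tmp_path):
        cfg = SimConfig(mode="clustered", seed=4)
        sample = simulate_sample(cfg, "s")
        paths = write_sample(sample, tmp_path)
        genome = cfg.genome()
        assert read_bedpe_svs(paths["bedpe"], genome) == sample.svs
        assert read_cn_segments(paths["cn"], genome) == sample.cn
        truth = json.loads((tmp_path / "s.truth.json").read_text())
        assert truth["truth_label"] == "balanced"
        assert truth["n_svs"] == len(sample.svs)
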
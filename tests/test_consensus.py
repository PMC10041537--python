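from collections import Counter

import numpy as np
import pytest

from duplexspectra import signatures
from duplexspectra.consensus import (
    DEFAULT_TRIM_RANGES,
    DCSRead,
    ReadFamily,
    SSCSRead,
    build_dcs,
    build_sscs,
    canonical_family_key,
    group_families,
    pair_and_filter,
    run_consensus,
    trim_dcs,
)
from duplexspectra.duplexsim import SPACER, SimulationConfig, simulate_molecules, simulate_reads


class TestCanonicalFamilyKey:
    def test_already_ordered_is_top(self):
        assert canonical_family_key("AAAA", "CCCC") == ("AAAA-CCCC", "top")

    def test_swapped_is_bottom_same_key(self):
        assert canonical_family_key("CCCC", "AAAA") == ("AAAA-CCCC", "bottom")

    def test_identical_tags_have_undefined_strand(self):
        key, strand = canonical_family_key("AAAA", "AAAA")
        assert key == "AAAA-AAAA"
        assert strand is None

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            canonical_family_key("AAA", "CCCC")


def _fastq(path, reads):
    """reads: list of (name, sequence)."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path


TAG_A, TAG_B = "AAAATTTTCCCC", "GGGGAAAATTTT"


class TestGroupFamilies:
    def test_complementary_tags_share_canonical_key(self, tmp_path):
        insert = "ACGT" * 10
        reads = [(f"t{i}", TAG_A + TAG_B + SPACER + insert) for i in range(3)]
        reads += [(f"b{i}", TAG_B + TAG_A + SPACER + insert) for i in range(3)]
        fams, stats = group_families(_fastq(tmp_path / "r1.fq", reads))
        assert stats["reads_total"] == 6
        assert len(fams) == 2
        assert {f.strand for f in fams} == {"top", "bottom"}
        assert len({f.canonical_key for f in fams}) == 1
        assert all(len(f.members) == 3 for f in fams)

    def test_corrupted_spacer_excluded_and_counted(self, tmp_path):
        good = TAG_A + TAG_B + SPACER + "ACGT" * 10
        bad = TAG_A + TAG_B + "XXXXX" + "ACGT" * 10
        fams, stats = group_families(
            _fastq(tmp_path / "r1.fq", [("g", good), ("g2", good), ("b", bad)])
        )
        assert stats["reads_malformed"] == 1
        assert sum(len(f.members) for f in fams) == 2

    def test_mostly_malformed_aborts(self, tmp_path):
        bad = "ACGT" * 12
        with pytest.raises(RuntimeError, match="unparseable"):
            group_families(_fastq(tmp_path / "r1.fq", [("b1", bad), ("b2", bad)]))

    def test_matches_simulator_truth_family_count(self, region6382, tmp_path):
        cfg = SimulationConfig(
            spectrum=signatures.sbs11_like(), n_molecules=150,
            mutation_rate=0.0, per_base_error_rate=0.0, family_size_min=1, seed=8,
        )
        mols = simulate_molecules(cfg, region6382)
        stats = simulate_reads(mols, region6382, cfg,
                               tmp_path / "r1.fq", tmp_path / "r2.fq")
        fams, gstats = group_families(tmp_path / "r1.fq", tmp_path / "r2.fq")
        truth = stats["truth"]
        expected = int(
            2 * (truth["n_top_reads"] > 0).sum() + 2 * (truth["n_bottom_reads"] > 0).sum()
        )  # one family per strand per mate
        assert gstats["families"] == expected


class TestBuildSSCS:
    def test_identical_reads(self):
        fam = ReadFamily("k", "top", None, ["ACGTT"] * 3)
        s = build_sscs(fam)
        assert s.sequence == "ACGTT"
        assert s.family_size == 3
        assert "N" not in s.sequence

    def test_split_below_threshold_masks(self):
        # 3A/2C at position 0: 0.6 < 0.7 -> N
        fam = ReadFamily("k", "top", None, ["AC", "AC", "AC", "CC", "CC"])
        assert build_sscs(fam).sequence == "NC"

    def test_split_at_threshold_accepts(self):
        # 7A/3C: 0.7 >= 0.7 -> A
        fam = ReadFamily("k", "top", None, ["A"] * 7 + ["C"] * 3)
        assert build_sscs(fam).sequence == "A"

    def test_tie_masks(self):
        fam = ReadFamily("k", "top", None, ["AG", "CG", "AG", "CG"])
        assert build_sscs(fam, consensus_threshold=0.5).sequence == "NG"

    def test_small_family_rejected(self):
        fam = ReadFamily("k", "top", None, ["ACG", "ACG"])
        assert build_sscs(fam, min_family_size=3) is None

    def test_unequal_lengths_rejected(self):
        fam = ReadFamily("k", "top", None, ["ACG", "ACGT", "ACG"])
        with pytest.raises(ValueError, match="unequal length"):
            build_sscs(fam)

    def test_agrees_with_brute_force_tally_oracle(self):
        rng = np.random.default_rng(0)
        threshold = 0.7
        for _ in range(1000):
            n = int(rng.integers(1, 7))
            L = int(rng.integers(1, 12))
            members = [
                "".join(rng.choice(list("ACGT"), size=L)) for _ in range(n)
            ]
            got = build_sscs(
                ReadFamily("k", "top", None, members),
                min_family_size=1,
                consensus_threshold=threshold,
            ).sequence
            expected = []
            for pos in range(L):
                tally = Counter(m[pos] for m in members)
                (base, count), = tally.most_common(1)
                ties = [b for b, c in tally.items() if c == count]
                if len(ties) > 1 or count / n < threshold:
                    expected.append("N")
                else:
                    expected.append(base)
            assert got == "".join(expected)


class TestBuildDCS:
    def _sscs(self, seq, strand, key="k"):
        return SSCSRead(key, strand, seq, family_size=3)

    def test_identical_pair(self):
        d = build_dcs(self._sscs("ACGT", "top"), self._sscs("ACGT", "bottom"))
        assert d.sequence == "ACGT"
        assert d.n_masked == 0

    def test_disagreement_masked(self):
        d = build_dcs(self._sscs("ACGT", "top"), self._sscs("AGGT", "bottom"))
        assert d.sequence == "ANGT"
        assert d.n_masked == 1

    def test_n_propagates(self):
        d = build_dcs(self._sscs("NCGT", "top"), self._sscs("ACGT", "bottom"))
        assert d.sequence == "NCGT"

    def test_reject_on_disagreement_switch(self):
        assert (
            build_dcs(
                self._sscs("ACGT", "top"), self._sscs("AGGT", "bottom"),
                reject_on_disagreement=True,
            )
            is None
        )

    def test_key_and_strand_checks(self):
        with pytest.raises(ValueError, match="key mismatch"):
            build_dcs(self._sscs("AC", "top", "k1"), self._sscs("AC", "bottom", "k2"))
        with pytest.raises(ValueError, match="one top and one bottom"):
            build_dcs(self._sscs("AC", "top"), self._sscs("AC", "top"))


class TestPairAndFilter:
    def test_pairs_top_and_bottom(self):
        sscs = [
            SSCSRead("k", "top", "ACGT", 3),
            SSCSRead("k", "bottom", "ACGT", 4),
        ]
        dcs, unpaired = pair_and_filter(sscs)
        assert len(dcs) == 1
        assert unpaired == 0

    def test_singleton_is_unpaired(self):
        dcs, unpaired = pair_and_filter([SSCSRead("k", "top", "ACGT", 3)])
        assert dcs == []
        assert unpaired == 1

    def test_paired_end_windows(self):
        # with mates, top/R1 pairs with bottom/R2 (left window) and
        # top/R2 with bottom/R1 (right window)
        sscs = [
            SSCSRead("k", "top", "AAAA", 3, mate=1),
            SSCSRead("k", "bottom", "AAAA", 3, mate=2),
            SSCSRead("k", "top", "CCCC", 3, mate=2),
            SSCSRead("k", "bottom", "CCCC", 3, mate=1),
        ]
        dcs, unpaired = pair_and_filter(sscs)
        assert unpaired == 0
        assert sorted(d.window for d in dcs) == ["left", "right"]


class TestTrim:
    def test_default_ranges_keep_111_positions(self):
        d = DCSRead("k", "A" * 137, 0)
        t = trim_dcs(d)
        assert len(t.sequence) == 137
        assert sum(b != "N" for b in t.sequence) == 111
        assert t.sequence[:8] == "N" * 8
        assert t.sequence[119:] == "N" * 18

    def test_empty_ranges_identity(self):
        d = DCSRead("k", "ACGT", 0)
        assert trim_dcs(d, ()).sequence == "ACGT"

    def test_out_of_bounds_range(self):
        with pytest.raises(ValueError, match="outside read"):
            trim_dcs(DCSRead("k", "ACGT", 0), ((1, 10),))

    def test_overlapping_ranges(self):
        with pytest.raises(ValueError, match="overlaps"):
            trim_dcs(DCSRead("k", "A" * 20, 0), ((1, 8), (5, 12)))


def _simulate_small(region, tmp_path, seed=21, **kw):
    cfg = SimulationConfig(
        spectrum=signatures.sbs11_like(), n_molecules=120, mutation_rate=1e-3,
        per_base_error_rate=1e-3, seed=seed, **kw,
    )
    mols = simulate_molecules(cfg, region)
    simulate_reads(mols, region, cfg, tmp_path / "r1.fq", tmp_path / "r2.fq")
    return cfg


class TestEndToEndProperties:
    def test_orientation_invariance_under_tag_swap(self, region6382, tmp_path):
        """Swapping the two tag arms of every read must not change any DCS."""
        _simulate_small(region6382, tmp_path)
        for name in ("r1.fq", "r2.fq"):
            lines = (tmp_path / name).read_text().splitlines()
            swapped = []
            for i, line in enumerate(lines):
                if i % 4 == 1:
                    line = line[12:24] + line[:12] + line[24:]
                swapped.append(line)
            (tmp_path / ("sw_" + name)).write_text("\n".join(swapped) + "\n")
        dcs_a, _ = run_consensus(tmp_path / "r1.fq", tmp_path / "r2.fq")
        dcs_b, _ = run_consensus(tmp_path / "sw_r1.fq", tmp_path / "sw_r2.fq")
        assert sorted(d.sequence for d in dcs_a) == sorted(d.sequence for d in dcs_b)

    def test_monotone_stringency(self, region6382, tmp_path):
        """Stricter family-size or agreement settings never add DCS bases."""
        _simulate_small(region6382, tmp_path, seed=22)

        def non_n_bases(**kw):
            dcs, _ = run_consensus(tmp_path / "r1.fq", tmp_path / "r2.fq", **kw)
            return sum(len(d.sequence) - d.n_masked for d in dcs)

        base = non_n_bases(min_family_size=2, consensus_threshold=0.6)
        assert non_n_bases(min_family_size=4, consensus_threshold=0.6) <= base
        assert non_n_bases(min_family_size=2, consensus_threshold=0.9) <= base

    def test_report_counters_are_consistent(self, region6382, tmp_path):
        _simulate_small(region6382, tmp_path, seed=23)
        dcs, report = run_consensus(tmp_path / "r1.fq", tmp_path / "r2.fq")
        assert report["reads_total"] >= report["families"]
        assert report["families"] == (
            report["sscs_built"]
            + report["sscs_rejected_size"]
            + report["sscs_rejected_length"]
        )
        assert report["dcs_built"] == len(dcs)
        assert 2 * report["dcs_built"] + report["sscs_unpaired"] == report["sscs_built"]
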
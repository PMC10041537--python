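import hashlib

import numpy as np
import pytest

from duplexspectra import signatures
from duplexspectra.duplexsim import (
    ChannelSiteIndex,
    SimulationConfig,
    TrueMolecule,
    simulate_gpt_counts,
    simulate_molecules,
    simulate_reads,
    synthetic_reference,
)
from duplexspectra.refio import revcomp
from duplexspectra.spectrum import Spectrum96, channel_of


def _cfg(**kw):
    defaults = dict(
        spectrum=signatures.sbs11_like(),
        n_molecules=50,
        mutation_rate=1e-3,
        per_base_error_rate=0.0,
        seed=3,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def _md5(path):
    return hashlib.md5(open(path, "rb").read()).hexdigest()


class TestSimulateMolecules:
    def test_zero_rate_gives_no_mutations(self, region6382):
        mols = simulate_molecules(_cfg(mutation_rate=0.0), region6382)
        assert all(not m.mutations for m in mols)

    def test_deterministic_given_seed(self, region6382):
        a = simulate_molecules(_cfg(), region6382)
        b = simulate_molecules(_cfg(), region6382)
        assert a == b

    def test_fragment_geometry(self, region6382):
        for m in simulate_molecules(_cfg(n_molecules=200), region6382):
            assert 0 <= m.start < m.end <= region6382.length
            assert 300 <= m.end - m.start <= 350
            for pos, ref, alt in m.mutations:
                assert m.start <= pos < m.end
                assert region6382.sequence[pos] == ref
                assert alt != ref

    def test_concentrated_spectrum_hits_matching_contexts_only(self, region6382):
        # all mass on one channel -> every injected site must carry that
        # context on one strand (checked against a brute-force inventory)
        channel = "A[C>T]G"
        spec = Spectrum96.from_frequency({channel: 1.0})
        mols = simulate_molecules(
            _cfg(spectrum=spec, mutation_rate=5e-3, n_molecules=400), region6382
        )
        seq = region6382.sequence
        sites = {
            i for i in range(1, len(seq) - 1)
            if seq[i - 1 : i + 2] in ("ACG", revcomp("ACG"))
        }
        injected = [(p, r, a) for m in mols for p, r, a in m.mutations]
        assert injected, "expected some injected mutations"
        for pos, ref, alt in injected:
            assert pos in sites
            assert channel_of(ref, alt, seq[pos - 1 : pos + 2]) == channel

    def test_unmatchable_channel_renormalized_with_warning(self):
        region = synthetic_reference(length=500, seed=9)
        # remove every ACG/CGT context so the A[C>T]G channel has no site
        seq = region.sequence.replace("ACG", "ATG").replace("CGT", "CAT")
        region = type(region)(name="r", sequence=seq)
        spec = Spectrum96.from_frequency({"A[C>T]G": 0.5, "T[T>C]G": 0.5})
        with pytest.warns(UserWarning, match="renormalizing"):
            mols = simulate_molecules(
                _cfg(spectrum=spec, mutation_rate=5e-3, n_molecules=100,
                     fragment_length_range=(300, 350)),
                region,
            )
        for m in mols:
            for p, r, a in m.mutations:
                assert channel_of(r, a, seq[p - 1 : p + 2]) == "T[T>C]G"


class TestSimulateReads:
    def test_byte_identical_given_seed(self, region6382, tmp_path):
        cfg = _cfg(per_base_error_rate=1e-3)
        mols = simulate_molecules(cfg, region6382)
        for tag in ("a", "b"):
            simulate_reads(
                mols, region6382, cfg,
                tmp_path / f"r1_{tag}.fq", tmp_path / f"r2_{tag}.fq",
                tmp_path / f"truth_{tag}.tsv",
            )
        assert _md5(tmp_path / "r1_a.fq") == _md5(tmp_path / "r1_b.fq")
        assert _md5(tmp_path / "r2_a.fq") == _md5(tmp_path / "r2_b.fq")
        assert _md5(tmp_path / "truth_a.tsv") == _md5(tmp_path / "truth_b.tsv")

    def test_error_free_reads_are_reference_substrings(self, region6382, tmp_path):
        cfg = _cfg(mutation_rate=0.0, per_base_error_rate=0.0, n_molecules=30)
        mols = simulate_molecules(cfg, region6382)
        simulate_reads(mols, region6382, cfg, tmp_path / "r1.fq", tmp_path / "r2.fq")
        prefix = 2 * cfg.tag_length + len(cfg.spacer)
        ref = region6382.sequence
        ref_rc = revcomp(ref)
        n_reads = 0
        for fq in ("r1.fq", "r2.fq"):
            lines = (tmp_path / fq).read_text().splitlines()
            for i in range(1, len(lines), 4):
                insert = lines[i][prefix:]
                assert insert in ref or insert in ref_rc
                n_reads += 1
        assert n_reads > 0

    def test_true_mutation_present_in_every_read_of_both_strands(
        self, region6382, tmp_path
    ):
        cfg = _cfg(mutation_rate=0.0, per_base_error_rate=0.0,
                   family_size_min=2, n_molecules=1)
        start = 1000
        pos = start + 50
        ref = region6382.sequence[pos]
        alt = "A" if ref != "A" else "G"
        mol = TrueMolecule(0, region6382.name, start, start + 320,
                           mutations=[(pos, ref, alt)])
        simulate_reads([mol], region6382, cfg, tmp_path / "r1.fq", tmp_path / "r2.fq")
        prefix = 2 * cfg.tag_length + len(cfg.spacer)
        from duplexspectra.refio import COMPLEMENT

        checked = 0
        for fq in ("r1.fq",):
            lines = (tmp_path / fq).read_text().splitlines()
            for i in range(0, len(lines), 4):
                strand = lines[i].split("strand=")[1]
                insert = lines[i + 1][prefix:]
                if strand == "top":
                    assert insert[50] == alt  # offset of pos in the left window
                else:
                    # bottom read1 covers the right fragment end, reverse
                    # complemented: position pos maps to end-1-pos
                    off = (start + 320 - 1) - pos
                    if off < len(insert):
                        assert insert[off] == COMPLEMENT[alt]
                checked += 1
        assert checked > 0

    def test_raw_error_rate_matches_binomial_expectation(self, region6382, tmp_path):
        rate = 1e-3
        cfg = _cfg(mutation_rate=0.0, per_base_error_rate=rate,
                   n_molecules=400, family_size_mean=2.0, family_size_min=1)
        mols = simulate_molecules(cfg, region6382)
        simulate_reads(mols, region6382, cfg, tmp_path / "r1.fq", tmp_path / "r2.fq")
        prefix = 2 * cfg.tag_length + len(cfg.spacer)
        ref = region6382.sequence
        ref_rc = revcomp(ref)
        mol_by_id = {m.mol_id: m for m in mols}
        mismatches = total = 0
        for fq, mate in (("r1.fq", 1), ("r2.fq", 2)):
            lines = (tmp_path / fq).read_text().splitlines()
            for i in range(0, len(lines), 4):
                strand = lines[i].split("strand=")[1]
                mol_id = int(lines[i].split(":")[0].lstrip("@m"))
                m = mol_by_id[mol_id]
                insert = lines[i + 1][prefix:]
                frag = ref[m.start : m.end]
                if (strand == "top") == (mate == 1):
                    expected = frag[: len(insert)]
                else:
                    expected = revcomp(frag)[: len(insert)]
                mismatches += sum(a != b for a, b in zip(insert, expected))
                total += len(insert)
        assert total >= 1e5
        sd = np.sqrt(total * rate * (1 - rate))
        assert abs(mismatches - total * rate) < 3 * sd


class TestGptCounts:
    def test_zero_mf_gives_zero_counts(self):
        df = simulate_gpt_counts(0.0, 10, seed=1)
        assert (df["tg_resistant"] == 0).all()

    def test_deterministic(self):
        a = simulate_gpt_counts(3e-5, 20, dispersion=0.1, seed=4)
        b = simulate_gpt_counts(3e-5, 20, dispersion=0.1, seed=4)
        assert a.equals(b)

    def test_mean_mf_recovered_at_n50(self):
        df = simulate_gpt_counts(3e-5, 50, dispersion=0.1, seed=2)
        mf = (df["tg_resistant"] / df["cm_resistant_mean"]).mean()
        assert abs(mf - 3e-5) / 3e-5 < 0.2

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            simulate_gpt_counts(1.5, 5)


class TestConfigValidation:
    def test_read_longer_than_fragment(self, region6382):
        with pytest.raises(ValueError, match="read_length"):
            _cfg(read_length=400).validate(region6382)

    def test_region_shorter_than_fragment(self):
        region = synthetic_reference(length=200, seed=1)
        with pytest.raises(ValueError, match="shorter than"):
            _cfg().validate(region)

    def test_bad_rates(self):
        with pytest.raises(ValueError):
            _cfg(mutation_rate=1.5).validate()
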
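"""Synthetic duplex-sequencing data generator.

Emulates the raw input of a duplex experiment on a short reporter target:
double-stranded fragments (300-350 bp) are drawn from the reference, true
mutations are injected per a 96-channel sampling spectrum, both strands of
each fragment are amplified into read families carrying duplex molecular
tags, and independent per-strand artifacts are sprinkled at a configurable
rate.  True duplex consensus must suppress the artifacts while retaining the
injected mutations.

Tag convention: each molecule draws two random tag arms (alpha, beta).
Reads derived from the top strand are prefixed with ``alpha+beta``, reads
from the bottom strand with ``beta+alpha``, followed by a fixed 5-nt spacer
— so complementary families are recognizable purely from the read sequence,
and the consensus stage has to do real tag parsing.  Quality strings are
constant ("I"): the downstream consensus uses agreement, not qualities.

Each read pair covers the two ends of the fragment: read 1 is the first
``read_length`` bases of the originating strand (5'->3'), read 2 the first
``read_length`` bases of the opposite strand.  Bottom-strand reads are
therefore reverse-complemented relative to the reference, and family
grouping/placement must canonicalize orientation.

All randomness flows from ``SimulationConfig.seed``; identical config and
seed give byte-identical FASTQ output.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import spectrum as spx
from .refio import ReferenceRegion, revcomp

#: Fixed spacer between the tag pair and the insert.
SPACER = "TGACT"
_BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Full parameterization of the generator.

    ``family_size_mean``/``family_size_min`` define the per-strand read-pair
    count distribution (Poisson truncated below at ``family_size_min``;
    the default min of 0 allows zero-read strands, which downstream must
    flag as unpaired).
    """

    spectrum: spx.Spectrum96
    n_molecules: int = 1000
    mutation_rate: float = 1e-4
    fragment_length_range: tuple[int, int] = (300, 350)
    read_length: int = 137
    family_size_mean: float = 5.0
    family_size_min: int = 0
    per_base_error_rate: float = 1e-3
    tag_length: int = 12
    spacer: str = SPACER
    seed: int = 0

    def validate(self, region: ReferenceRegion | None = None) -> None:
        lo, hi = self.fragment_length_range
        if not (0 < lo <= hi):
            raise ValueError(f"bad fragment_length_range {self.fragment_length_range}")
        if self.read_length > lo:
            raise ValueError("read_length exceeds the minimum fragment length")
        for attr in ("mutation_rate", "per_base_error_rate"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} must be in [0, 1], got {v}")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.tag_length < 1:
            raise ValueError("tag_length must be >= 1")
        if self.family_size_min < 0 or self.family_size_mean <= 0:
            raise ValueError("bad family size distribution parameters")
        if abs(self.spectrum.vector.sum() - 1.0) > 1e-9:
            raise ValueError("spectrum frequencies must sum to 1")
        if region is not None and region.length <= hi:
            raise ValueError(
                f"region {region.name!r} (length {region.length}) shorter than "
                f"the maximum fragment length {hi}"
            )


@dataclass
class TrueMolecule:
    """A simulated double-stranded fragment with its injected mutations."""

    mol_id: int
    region: str
    start: int  # 0-based
    end: int    # half-open
    mutations: list[tuple[int, str, str]] = field(default_factory=list)
    # (reference position, ref base, alt base) on the top/reference strand


def synthetic_reference(
    length: int = 6382, gc: float = 0.5, seed: int = 2023, name: str = "synthetic_target"
) -> ReferenceRegion:
    """Seeded random reference region — a synthetic stand-in for a reporter
    target of the same length (the real target sequence is not shipped)."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(_BASES[i] for i in rng.choice(4, size=length, p=p))
    return ReferenceRegion(name=name, sequence=seq)


class ChannelSiteIndex:
    """Inventory of every (position, ref, alt) substitution in a region,
    bucketed by spectrum channel (both strands, via the pyrimidine fold)."""

    def __init__(self, region: ReferenceRegion):
        self.region = region
        positions: dict[str, list[int]] = {c: [] for c in spx.CHANNELS}
        alts: dict[str, list[str]] = {c: [] for c in spx.CHANNELS}
        seq = region.sequence
        for pos in range(1, region.length - 1):
            ctx = seq[pos - 1 : pos + 2]
            ref = ctx[1]
            for alt in _BASES:
                if alt == ref:
                    continue
                ch = spx.channel_of(ref, alt, ctx)
                positions[ch].append(pos)
                alts[ch].append(alt)
        self.positions = {c: np.asarray(v, dtype=np.int64) for c, v in positions.items()}
        self.alts = {c: np.asarray(v) for c, v in alts.items()}

    def n_sites(self, channel: str) -> int:
        return len(self.positions[channel])


def simulate_molecules(
    config: SimulationConfig,
    region: ReferenceRegion,
    site_index: ChannelSiteIndex | None = None,
) -> list[TrueMolecule]:
    """Draw fragments and inject true mutations.

    Fragment starts are uniform over valid offsets, lengths uniform over
    ``fragment_length_range``.  The number of mutations per molecule is
    Binomial(length, mutation_rate); each mutation first draws a channel
    from the spectrum, then a concrete site uniformly among the fragment's
    reference positions whose context matches that channel (either strand).
    Channels with spectrum mass but no matching site anywhere in the region
    trigger a warning and are renormalized away; a channel with no matching
    site inside one particular fragment is simply redrawn.
    """
    config.validate(region)
    if site_index is None:
        site_index = ChannelSiteIndex(region)
    rng = np.random.default_rng([config.seed, 0])

    probs = config.spectrum.vector.copy()
    empty = np.array([site_index.n_sites(c) == 0 for c in spx.CHANNELS])
    dead = probs[empty].sum()
    if dead > 0:
        warnings.warn(
            f"{int(empty.sum())} spectrum channel(s) with mass {dead:.3g} have no "
            f"matching site in region {region.name!r}; renormalizing"
        )
        probs[empty] = 0.0
        probs = probs / probs.sum()

    lo, hi = config.fragment_length_range
    n = config.n_molecules
    lengths = rng.integers(lo, hi + 1, size=n)
    starts = rng.integers(0, region.length - lengths + 1)
    n_muts = (
        rng.binomial(lengths, config.mutation_rate)
        if config.mutation_rate > 0
        else np.zeros(n, dtype=int)
    )
    seq = region.sequence

    molecules = []
    for i in range(n):
        start, end = int(starts[i]), int(starts[i] + lengths[i])
        muts: list[tuple[int, str, str]] = []
        used: set[int] = set()
        for _ in range(int(n_muts[i])):
            for _attempt in range(50):
                ch = spx.CHANNELS[rng.choice(96, p=probs)]
                pos_arr = site_index.positions[ch]
                i0 = int(np.searchsorted(pos_arr, start))
                i1 = int(np.searchsorted(pos_arr, end))
                if i0 == i1:
                    continue  # fragment lacks this context; redraw channel
                j = int(rng.integers(i0, i1))
                pos = int(pos_arr[j])
                if pos in used:
                    continue
                used.add(pos)
                muts.append((pos, seq[pos], str(site_index.alts[ch][j])))
                break
        muts.sort()
        molecules.append(
            TrueMolecule(mol_id=i, region=region.name, start=start, end=end, mutations=muts)
        )
    return molecules


def _random_tag(rng, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _inject_errors(insert: str, n_err: int, rng) -> str:
    if n_err == 0:
        return insert
    pos = rng.choice(len(insert), size=n_err, replace=False)
    s = bytearray(insert, "ascii")
    for p in pos:
        cur = chr(s[p])
        alts = [b for b in _BASES if b != cur]
        s[p] = ord(alts[rng.integers(3)])
    return s.decode()


def simulate_reads(
    molecules: list[TrueMolecule],
    region: ReferenceRegion,
    config: SimulationConfig,
    r1_path,
    r2_path,
    truth_path=None,
) -> dict:
    """Write tagged paired-end FASTQ files (and optionally a truth TSV).

    Every read of a molecule carries that molecule's true mutations
    (complement-adjusted on the bottom strand) plus independent per-base
    artifacts at ``per_base_error_rate``.  The truth TSV records, per
    molecule, the interval, tags, per-strand read-pair counts and injected
    mutations — the oracle for downstream recovery tests.
    """
    config.validate(region)
    rng = np.random.default_rng([config.seed, 1])
    L = config.read_length
    qual = "I" * (2 * config.tag_length + len(config.spacer) + L)
    seq = region.sequence

    def draw_family_size() -> int:
        while True:
            k = int(rng.poisson(config.family_size_mean))
            if k >= config.family_size_min:
                return k

    n_pairs = 0
    truth_rows = []
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for mol in molecules:
            frag = bytearray(seq[mol.start : mol.end], "ascii")
            for pos, ref, alt in mol.mutations:
                if frag[pos - mol.start] != ord(ref):
                    raise ValueError(
                        f"molecule {mol.mol_id}: ref mismatch at position {pos}"
                    )
                frag[pos - mol.start] = ord(alt)
            frag_top = frag.decode()
            frag_bot = revcomp(frag_top)

            alpha = _random_tag(rng, config.tag_length)
            beta = _random_tag(rng, config.tag_length)
            while beta == alpha:  # identical arms make strand assignment ambiguous
                beta = _random_tag(rng, config.tag_length)

            n_top = draw_family_size()
            n_bot = draw_family_size()
            for strand, n_reads, prefix, r1_insert, r2_insert in (
                ("top", n_top, alpha + beta, frag_top[:L], frag_bot[:L]),
                ("bottom", n_bot, beta + alpha, frag_bot[:L], frag_top[:L]),
            ):
                if n_reads == 0:
                    continue
                errs = (
                    rng.binomial(L, config.per_base_error_rate, size=2 * n_reads)
                    if config.per_base_error_rate > 0
                    else np.zeros(2 * n_reads, dtype=int)
                )
                for r in range(n_reads):
                    s1 = _inject_errors(r1_insert, int(errs[2 * r]), rng)
                    s2 = _inject_errors(r2_insert, int(errs[2 * r + 1]), rng)
                    name = f"m{mol.mol_id}:{strand}:{r}"
                    f1.write(f"@{name}/1 strand={strand}\n{prefix}{config.spacer}{s1}\n+\n{qual}\n")
                    f2.write(f"@{name}/2 strand={strand}\n{prefix}{config.spacer}{s2}\n+\n{qual}\n")
                    n_pairs += 1
            truth_rows.append(
                {
                    "mol_id": mol.mol_id,
                    "region": mol.region,
                    "start": mol.start,
                    "end": mol.end,
                    "tag_alpha": alpha,
                    "tag_beta": beta,
                    "n_top_reads": n_top,
                    "n_bottom_reads": n_bot,
                    "mutations": ";".join(f"{p}:{r}:{a}" for p, r, a in mol.mutations)
                    or ".",
                }
            )
    truth = pd.DataFrame(truth_rows)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return {"n_molecules": len(molecules), "n_read_pairs": n_pairs, "truth": truth}


def parse_truth_mutations(field: str) -> list[tuple[int, str, str]]:
    """Decode the truth TSV ``mutations`` column ('.' means none)."""
    if field == "." or field == "" or pd.isna(field):
        return []
    out = []
    for item in str(field).split(";"):
        p, r, a = item.split(":")
        out.append((int(p), r, a))
    return out


def simulate_gpt_counts(
    true_mf: float,
    n_animals: int,
    dispersion: float = 0.0,
    seed: int = 0,
    titer_mean: float = 2e6,
    titer_sigma: float = 0.25,
    group: str = "treated",
) -> pd.DataFrame:
    """Synthetic colony-count table for a reporter fluctuation assay.

    Per animal, the selectable titer (chloramphenicol-resistant colony
    equivalent) is lognormal around ``titer_mean``; the mutant count
    (6-thioguanine-resistant colonies) is Poisson with mean
    ``titer * true_mf``, optionally gamma-overdispersed (``dispersion`` is
    the extra squared coefficient of variation; 0 = pure Poisson).
    """
    if not 0.0 <= true_mf < 1.0:
        raise ValueError(f"true_mf must be in [0, 1), got {true_mf}")
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    mu = np.log(titer_mean) - titer_sigma**2 / 2  # mean of lognormal == titer_mean
    titer = rng.lognormal(mu, titer_sigma, size=n_animals)
    lam = titer * true_mf
    if dispersion > 0:
        lam = lam * rng.gamma(1.0 / dispersion, dispersion, size=n_animals)
    tg = rng.poisson(lam)
    return pd.DataFrame(
        {
            "animal": [f"{group}_{i + 1}" for i in range(n_animals)],
            "group": group,
            "tg_resistant": tg.astype(int),
            "cm_resistant_mean": titer,
        }
    )
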
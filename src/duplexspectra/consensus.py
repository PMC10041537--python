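"""Duplex consensus calling: tag parsing, family grouping, single-strand
consensus (SSCS), double-strand consensus (DCS) and end trimming.

The acceptance rule is the duplex one: a base enters the DCS only when the
consensus of each strand's read family exists at that position and the two
strands agree exactly.  Disagreements are masked to ``N`` at base resolution
(coordinates are preserved); whole-read rejection on any disagreement is
available via ``reject_on_disagreement``.  Unpaired single-strand families
are flagged and dropped.

Tags must match exactly — there is no tag-error correction or clustering.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .duplexsim import SPACER

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

#: Default mask-trim ranges, 1-based inclusive, chosen for 137-nt consensus
#: reads: drop bases 1-8 and 120-137, keeping the 111-nt window 9-119.
DEFAULT_TRIM_RANGES = ((1, 8), (120, 137))


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A,C,G,T -> 0..3; anything else -> 4)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


@dataclass
class ReadFamily:
    canonical_key: str
    strand: str  # "top" | "bottom"
    mate: int | None
    members: list[str] = field(default_factory=list)


@dataclass
class SSCSRead:
    canonical_key: str
    strand: str
    sequence: str
    family_size: int
    mate: int | None = None


@dataclass
class DCSRead:
    canonical_key: str
    sequence: str
    n_masked: int
    window: str = "only"


def canonical_family_key(tag_alpha: str, tag_beta: str) -> tuple[str, str | None]:
    """Orientation-invariant family key.

    ``(a, b)`` and ``(b, a)`` map to the same key with opposite strand
    labels (lexicographically smaller arm first; "top" when the input order
    is already canonical).  Identical arms leave the strand undefined
    (returned as ``None``); such families are dropped by the grouper.
    """
    if not tag_alpha or not tag_beta:
        raise ValueError("tags must be non-empty")
    if len(tag_alpha) != len(tag_beta):
        raise ValueError(
            f"tag length mismatch: {len(tag_alpha)} vs {len(tag_beta)}"
        )
    if tag_alpha == tag_beta:
        return f"{tag_alpha}-{tag_beta}", None
    if tag_alpha < tag_beta:
        return f"{tag_alpha}-{tag_beta}", "top"
    return f"{tag_beta}-{tag_alpha}", "bottom"


def group_families(
    r1_path,
    r2_path=None,
    tag_length: int = 12,
    spacer: str = SPACER,
) -> tuple[list[ReadFamily], dict]:
    """Assemble tagged reads into strand families.

    Each read must start with the two tag arms followed by the fixed spacer;
    reads with an unparseable prefix (wrong spacer, non-ACGT tag, too short)
    are excluded and counted.  Reads whose two tag arms are identical cannot
    be assigned a strand and are likewise dropped.  A malformed fraction
    above 50% aborts with a diagnostic.
    """
    stats = {
        "reads_total": 0,
        "reads_malformed": 0,
        "reads_identical_tags": 0,
    }
    prefix_len = 2 * tag_length + len(spacer)
    families: dict[tuple[str, str, int | None], list[str]] = {}

    sources = [(1, r1_path)]
    if r2_path is not None:
        sources.append((2, r2_path))
    for mate, path in sources:
        with open(path) as handle:
            for _title, seq, _qual in FastqGeneralIterator(handle):
                stats["reads_total"] += 1
                seq = seq.upper()
                if len(seq) <= prefix_len or seq[2 * tag_length : prefix_len] != spacer:
                    stats["reads_malformed"] += 1
                    continue
                a = seq[:tag_length]
                b = seq[tag_length : 2 * tag_length]
                if not set(a + b) <= set("ACGT"):
                    stats["reads_malformed"] += 1
                    continue
                key, strand = canonical_family_key(a, b)
                if strand is None:
                    stats["reads_identical_tags"] += 1
                    continue
                fam_mate = mate if r2_path is not None else None
                families.setdefault((key, strand, fam_mate), []).append(seq[prefix_len:])

    if stats["reads_total"] and stats["reads_malformed"] / stats["reads_total"] > 0.5:
        raise RuntimeError(
            f"{stats['reads_malformed']} of {stats['reads_total']} reads have "
            f"unparseable tag/spacer prefixes; check tag_length/spacer settings"
        )
    out = [
        ReadFamily(canonical_key=k, strand=s, mate=m, members=members)
        for (k, s, m), members in sorted(families.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2] or 0))
    ]
    stats["families"] = len(out)
    return out, stats


def build_sscs(
    family: ReadFamily,
    min_family_size: int = 3,
    consensus_threshold: float = 0.7,
) -> SSCSRead | None:
    """Collapse one read family into a single-strand consensus.

    Families below ``min_family_size`` are rejected (``None``).  Per
    position, the plurality base is accepted when its fraction of family
    members is >= ``consensus_threshold``; ties and sub-threshold positions
    become ``N``.  Members of unequal length reject the family with a
    diagnostic.
    """
    n = len(family.members)
    if n == 0:
        raise ValueError("empty family")
    if n < min_family_size:
        return None
    lengths = {len(m) for m in family.members}
    if len(lengths) != 1:
        raise ValueError(
            f"family {family.canonical_key!r}/{family.strand}: members of "
            f"unequal length {sorted(lengths)}"
        )
    arr = encode("".join(family.members)).reshape(n, -1)
    counts = np.stack([(arr == b).sum(axis=0) for b in range(4)])  # (4, L)
    best_count = counts.max(axis=0)
    best_base = counts.argmax(axis=0)
    tied = (counts == best_count).sum(axis=0) > 1
    ok = (~tied) & (best_count / n >= consensus_threshold)
    cons = np.where(ok, best_base, 4).astype(np.uint8)
    return SSCSRead(
        canonical_key=family.canonical_key,
        strand=family.strand,
        sequence=decode(cons),
        family_size=n,
        mate=family.mate,
    )


def build_dcs(
    sscs_top: SSCSRead,
    sscs_bottom: SSCSRead,
    reject_on_disagreement: bool = False,
) -> DCSRead | None:
    """Combine two complementary strand consensuses, keeping only perfect
    agreement.

    Both inputs must share the canonical key, carry opposite strand labels
    and (already co-oriented) equal lengths.  Positions where either strand
    is ``N`` or the strands differ are masked to ``N``; with
    ``reject_on_disagreement`` any true base conflict drops the read pair
    entirely (``None``).
    """
    if sscs_top.canonical_key != sscs_bottom.canonical_key:
        raise ValueError("canonical key mismatch")
    if {sscs_top.strand, sscs_bottom.strand} != {"top", "bottom"}:
        raise ValueError(
            f"need one top and one bottom SSCS, got "
            f"{sscs_top.strand!r}/{sscs_bottom.strand!r}"
        )
    if len(sscs_top.sequence) != len(sscs_bottom.sequence):
        raise ValueError("SSCS length mismatch")
    a = encode(sscs_top.sequence)
    b = encode(sscs_bottom.sequence)
    conflict = (a < 4) & (b < 4) & (a != b)
    if reject_on_disagreement and conflict.any():
        return None
    cons = np.where((a == b) & (a < 4), a, 4).astype(np.uint8)
    return DCSRead(
        canonical_key=sscs_top.canonical_key,
        sequence=decode(cons),
        n_masked=int((cons == 4).sum()),
    )


def _window_of(strand: str, mate: int | None) -> str:
    """Which fragment end an SSCS covers.

    With paired-end data the top strand's read 1 and the bottom strand's
    read 2 cover the same fragment end in the same orientation (and vice
    versa); single-window data (``mate is None``) pairs top with bottom
    directly.
    """
    if mate is None:
        return "only"
    return "left" if (strand == "top") == (mate == 1) else "right"


def pair_and_filter(
    sscs_list: list[SSCSRead],
    reject_on_disagreement: bool = False,
) -> tuple[list[DCSRead], int]:
    """Pair complementary SSCS into DCS; count and drop unpaired ones."""
    groups: dict[tuple[str, str], list[SSCSRead]] = {}
    for s in sscs_list:
        groups.setdefault((s.canonical_key, _window_of(s.strand, s.mate)), []).append(s)
    dcs_reads: list[DCSRead] = []
    n_unpaired = 0
    for (key, window), members in sorted(groups.items()):
        tops = [m for m in members if m.strand == "top"]
        bottoms = [m for m in members if m.strand == "bottom"]
        if len(tops) == 1 and len(bottoms) == 1:
            d = build_dcs(tops[0], bottoms[0], reject_on_disagreement)
            if d is not None:
                d.window = window
                dcs_reads.append(d)
        else:
            n_unpaired += len(members)
    return dcs_reads, n_unpaired


def trim_dcs(
    dcs: DCSRead,
    ranges: tuple[tuple[int, int], ...] = DEFAULT_TRIM_RANGES,
) -> DCSRead:
    """Mask-trim DCS ends: positions in the given 1-based inclusive ranges
    become ``N`` (coordinates are preserved, so no downstream shift).

    With the defaults a 137-nt DCS keeps the 111 informative positions
    9-119.  Overlapping or out-of-bounds ranges raise.
    """
    L = len(dcs.sequence)
    mask = np.zeros(L, dtype=bool)
    for lo, hi in ranges:
        if not (1 <= lo <= hi <= L):
            raise ValueError(f"trim range ({lo}, {hi}) outside read of length {L}")
        if mask[lo - 1 : hi].any():
            raise ValueError(f"trim range ({lo}, {hi}) overlaps another range")
        mask[lo - 1 : hi] = True
    codes = encode(dcs.sequence)
    codes[mask] = 4
    return DCSRead(
        canonical_key=dcs.canonical_key,
        sequence=decode(codes),
        n_masked=int((codes == 4).sum()),
        window=dcs.window,
    )


def run_consensus(
    r1_path,
    r2_path=None,
    tag_length: int = 12,
    spacer: str = SPACER,
    min_family_size: int = 3,
    consensus_threshold: float = 0.7,
    trim_ranges: tuple[tuple[int, int], ...] = DEFAULT_TRIM_RANGES,
    reject_on_disagreement: bool = False,
) -> tuple[list[DCSRead], dict]:
    """Full consensus stage: group -> SSCS -> pair -> trim, with a report
    of every filtering counter."""
    families, stats = group_families(r1_path, r2_path, tag_length, spacer)
    sscs_list: list[SSCSRead] = []
    rejected_size = 0
    rejected_length = 0
    for fam in families:
        lengths = {len(m) for m in fam.members}
        if len(lengths) != 1:
            rejected_length += 1
            continue
        s = build_sscs(fam, min_family_size, consensus_threshold)
        if s is None:
            rejected_size += 1
        else:
            sscs_list.append(s)
    dcs_reads, n_unpaired = pair_and_filter(sscs_list, reject_on_disagreement)
    dcs_reads = [trim_dcs(d, trim_ranges) for d in dcs_reads]
    total_bases = sum(len(d.sequence) for d in dcs_reads)
    masked = sum(d.n_masked for d in dcs_reads)
    report = {
        **stats,
        "sscs_built": len(sscs_list),
        "sscs_rejected_size": rejected_size,
        "sscs_rejected_length": rejected_length,
        "sscs_unpaired": n_unpaired,
        "dcs_built": len(dcs_reads),
        "masked_base_fraction": masked / total_bases if total_bases else 0.0,
    }
    return dcs_reads, report


def write_dcs_fastq(dcs_reads: list[DCSRead], path) -> None:
    """DCS reads as FASTQ (constant qualities; name = key + window)."""
    with open(path, "w") as fh:
        for d in dcs_reads:
            fh.write(
                f"@{d.canonical_key}:{d.window}\n{d.sequence}\n+\n{'I' * len(d.sequence)}\n"
            )
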
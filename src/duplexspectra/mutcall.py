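"""Placement of DCS reads on the reference, pileup and mutation calling.

The placer is a deliberately simple exact-seed, ungapped aligner: duplex
consensus reads from a substitution-only process differ from the reference
by isolated mismatches, so k-mer seeding plus full-length identity scoring
is exact for this data.  Coordinate-sorted alignments produced externally
(for real gapped data) can be fed in as ready-made :class:`Placement`
objects instead.

Calls are collapsed to *unique* mutations — a substitution at a given site
counts once regardless of how many DCS molecules carry it, which removes
clonal-expansion weighting from downstream spectra.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus import DCSRead, encode
from .refio import ReferenceRegion, revcomp

_BASES = "ACGT"


@dataclass
class Placement:
    region: str
    start: int  # 0-based
    strand: str  # "+" | "-"
    identity: float


@dataclass
class PileupColumn:
    region: str
    pos: int  # 0-based
    ref: str
    depth: int
    alt_counts: dict[str, int]


@dataclass(frozen=True)
class MutationCall:
    region: str
    pos: int  # 0-based
    ref: str
    alt: str
    observation_count: int
    context3: str | None  # reference trinucleotide, None at region edges


class ReferenceIndex:
    """Exact k-mer index over one or more regions (forward strand; reverse
    placements are found by searching the reverse-complemented read)."""

    def __init__(self, regions, seed_length: int = 20):
        if isinstance(regions, ReferenceRegion):
            regions = [regions]
        self.seed_length = seed_length
        self.regions = {r.name: r for r in regions}
        self.encoded = {r.name: encode(r.sequence) for r in regions}
        self.kmers: dict[str, list[tuple[str, int]]] = {}
        for r in regions:
            seq = r.sequence
            for i in range(r.length - seed_length + 1):
                self.kmers.setdefault(seq[i : i + seed_length], []).append((r.name, i))


def _seed_offsets(codes: np.ndarray, k: int, max_seeds: int = 4) -> list[int]:
    """Start offsets of up to ``max_seeds`` disjoint non-N k-mers."""
    offsets = []
    run_start = None
    i = 0
    n = len(codes)
    while i <= n and len(offsets) < max_seeds:
        inside = i < n and codes[i] < 4
        if inside and run_start is None:
            run_start = i
        if (not inside) and run_start is not None:
            j = run_start
            while j + k <= i and len(offsets) < max_seeds:
                offsets.append(j)
                j += k
            run_start = None
        i += 1
    return offsets


def align_dcs(
    dcs: DCSRead | str,
    index: ReferenceIndex,
    min_identity: float = 0.9,
) -> Placement | None:
    """Place a DCS read by exact-seed lookup and ungapped extension.

    Both orientations are tried; the best placement by identity (matches
    over non-N read positions) wins.  No seed hit or identity below
    ``min_identity`` returns ``None`` (unmapped, counted by the caller).
    """
    seq = dcs.sequence if isinstance(dcs, DCSRead) else dcs
    k = index.seed_length
    L = len(seq)
    best: tuple[float, str, str, int] | None = None
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        codes = encode(oriented)
        nonn = codes < 4
        n_nonn = int(nonn.sum())
        if n_nonn < k:
            continue
        candidates: set[tuple[str, int]] = set()
        for off in _seed_offsets(codes, k):
            for rname, rpos in index.kmers.get(oriented[off : off + k], ()):
                start = rpos - off
                if start >= 0 and start + L <= index.regions[rname].length:
                    candidates.add((rname, start))
        for rname, start in sorted(candidates):
            ref_codes = index.encoded[rname][start : start + L]
            matches = int(((codes == ref_codes) & nonn).sum())
            identity = matches / n_nonn
            if best is None or identity > best[0]:
                best = (identity, strand, rname, start)
    if best is None or best[0] < min_identity:
        return None
    identity, strand, rname, start = best
    return Placement(region=rname, start=start, strand=strand, identity=identity)


def pileup(
    placed: list[tuple[DCSRead | str, Placement]],
    regions,
) -> list[PileupColumn]:
    """Stack placed DCS reads into per-position base counts.

    ``N`` bases contribute nothing; columns with zero depth are omitted.
    Reads placed on the reverse strand are re-oriented before counting, so
    all counts are in reference coordinates on the forward strand.
    """
    if isinstance(regions, ReferenceRegion):
        regions = [regions]
    region_map = {r.name: r for r in regions}
    mats = {r.name: np.zeros((r.length, 4), dtype=np.int64) for r in regions}
    for dcs, pl in placed:
        seq = dcs.sequence if isinstance(dcs, DCSRead) else dcs
        if pl.region not in region_map:
            raise ValueError(f"placement references unknown region {pl.region!r}")
        L = len(seq)
        if pl.start < 0 or pl.start + L > region_map[pl.region].length:
            raise ValueError(
                f"placement at {pl.start} inconsistent with region bounds"
            )
        oriented = seq if pl.strand == "+" else revcomp(seq)
        codes = encode(oriented)
        valid = codes < 4
        idx = pl.start + np.nonzero(valid)[0]
        np.add.at(mats[pl.region], (idx, codes[valid]), 1)
    columns: list[PileupColumn] = []
    for name in sorted(mats):
        mat = mats[name]
        seq = region_map[name].sequence
        for pos in np.nonzero(mat.sum(axis=1))[0]:
            ref = seq[pos]
            counts = mat[pos]
            alt_counts = {
                b: int(counts[i])
                for i, b in enumerate(_BASES)
                if b != ref and counts[i] > 0
            }
            columns.append(
                PileupColumn(
                    region=name,
                    pos=int(pos),
                    ref=ref,
                    depth=int(counts.sum()),
                    alt_counts=alt_counts,
                )
            )
    return columns


def call_mutations(columns: list[PileupColumn], regions) -> list[MutationCall]:
    """One call per (position, alt) with any supporting DCS base.

    No depth or allele-fraction threshold is applied: every DCS base is an
    independent molecule, and clonality is handled by the uniqueness
    collapse.  The trinucleotide context is taken from the reference, never
    from the reads; positions lacking a neighbor get ``context3=None`` and
    are excluded from spectra later.
    """
    if isinstance(regions, ReferenceRegion):
        regions = [regions]
    region_map = {r.name: r for r in regions}
    calls = []
    for col in columns:
        seq = region_map[col.region].sequence
        context = (
            seq[col.pos - 1 : col.pos + 2]
            if 1 <= col.pos <= len(seq) - 2
            else None
        )
        for alt in sorted(col.alt_counts):
            calls.append(
                MutationCall(
                    region=col.region,
                    pos=col.pos,
                    ref=col.ref,
                    alt=alt,
                    observation_count=col.alt_counts[alt],
                    context3=context,
                )
            )
    return calls


def unique_mutations(
    calls: list[MutationCall], by_position: bool = False
) -> list[MutationCall]:
    """Collapse repeated observations of the same substitution to one entry.

    The default key is (region, position, alt), which keeps two different
    substitutions at one site as two unique mutations and preserves spectrum
    channel integrity.  ``by_position=True`` applies the stricter
    one-mutation-per-site reading, keeping the most-observed alt (ties by
    alphabetical alt).
    """
    best: dict[tuple, MutationCall] = {}
    for c in calls:
        key = (c.region, c.pos) if by_position else (c.region, c.pos, c.alt)
        prev = best.get(key)
        if prev is None or (
            by_position
            and (c.observation_count, -ord(c.alt)) > (prev.observation_count, -ord(prev.alt))
        ):
            best[key] = c
    return [
        MutationCall(c.region, c.pos, c.ref, c.alt, 1, c.context3)
        for _k, c in sorted(best.items())
    ]


def place_and_call(
    dcs_reads: list[DCSRead],
    regions,
    seed_length: int = 20,
    min_identity: float = 0.9,
    by_position: bool = False,
):
    """Convenience driver: align, pile up, call, deduplicate.

    Returns ``(unique_calls, all_calls, report)`` where the report counts
    mapped/unmapped reads and informative DCS bases.
    """
    if isinstance(regions, ReferenceRegion):
        regions = [regions]
    index = ReferenceIndex(regions, seed_length=seed_length)
    placed = []
    n_unmapped = 0
    for d in dcs_reads:
        pl = align_dcs(d, index, min_identity=min_identity)
        if pl is None:
            n_unmapped += 1
        else:
            placed.append((d, pl))
    columns = pileup(placed, regions)
    calls = call_mutations(columns, regions)
    uniq = unique_mutations(calls, by_position=by_position)
    report = {
        "dcs_total": len(dcs_reads),
        "dcs_mapped": len(placed),
        "dcs_unmapped": n_unmapped,
        "dcs_bases": int(sum(col.depth for col in columns)),
        "calls_total": len(calls),
        "unique_mutations": len(uniq),
    }
    return uniq, calls, report


def mutations_to_frame(calls: list[MutationCall]) -> pd.DataFrame:
    """Mutation table with 1-based positions for export."""
    return pd.DataFrame(
        {
            "region": [c.region for c in calls],
            "pos": [c.pos + 1 for c in calls],
            "ref": [c.ref for c in calls],
            "alt": [c.alt for c in calls],
            "observations": [c.observation_count for c in calls],
            "context3": [c.context3 or "." for c in calls],
        }
    )


def mutations_to_tsv(calls: list[MutationCall], path) -> None:
    mutations_to_frame(calls).to_csv(path, sep="\t", index=False)


def mutations_from_tsv(path) -> list[MutationCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        MutationCall(
            region=row.region,
            pos=int(row.pos) - 1,
            ref=row.ref,
            alt=row.alt,
            observation_count=int(row.observations),
            context3=None if row.context3 == "." else row.context3,
        )
        for row in df.itertuples()
    ]


def mutations_to_vcf(calls: list[MutationCall], path) -> None:
    """Minimal substitution-only VCF export."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=duplexspectra\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.region, c.pos, c.alt)):
            fh.write(
                f"{c.region}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t"
                f"OBS={c.observation_count}\n"
            )
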
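"""Reference-region handling: FASTA loading, trinucleotide composition and
context windows.

Coordinates are 0-based, half-open everywhere inside the package; 1-based
coordinates appear only in exported tables and at the command line.  Targets
are short reporter regions (kilobases), so sequences are held in memory as
plain strings and no on-disk index is built.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGT")
_COMPLEMENT_TABLE = str.maketrans("ACGTN", "TGCAN")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: All 64 trinucleotides in alphabetical order.
TRINUCLEOTIDES = ["".join(p) for p in itertools.product("ACGT", repeat=3)]
#: The 32 pyrimidine-centered trinucleotides used for strand-collapsed counts.
PYRIMIDINE_TRINUCLEOTIDES = [t for t in TRINUCLEOTIDES if t[1] in "CT"]


class OutOfWindowError(ValueError):
    """A requested context window runs off the end of the region."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid base(s) {sorted(bad)!r} in sequence")
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


@dataclass(frozen=True)
class ReferenceRegion:
    """A named target region with an uppercase {A,C,G,T} sequence."""

    name: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def load_reference(path) -> list[ReferenceRegion]:
    """Load every record of a (multi-)FASTA file as a :class:`ReferenceRegion`.

    Sequences are uppercased.  Ambiguity codes are rejected outright rather
    than skipped: a curated kilobase-scale target should be clean, and a
    silent skip would hide upstream data problems.

    Raises
    ------
    ValueError
        If the file holds no records, or a record contains a non-ACGT
        character (the error names the record and the 0-based offset).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    regions = []
    for rec in records:
        seq = str(rec.seq).upper()
        if not VALID_BASES.issuperset(seq):
            for off, ch in enumerate(seq):
                if ch not in VALID_BASES:
                    raise ValueError(
                        f"record {rec.id!r}: invalid base {ch!r} at offset {off}"
                    )
        regions.append(ReferenceRegion(name=rec.id, sequence=seq))
    return regions


@dataclass(frozen=True)
class TrinucleotideComposition:
    """Trinucleotide occurrence counts of one or more regions.

    ``counts`` covers all 64 trinucleotides over interior positions only
    (no wraparound or padding), ``relative`` are the corresponding
    frequencies summing to 1, and ``collapsed`` folds the two strands onto
    the 32 pyrimidine-centered trinucleotides:
    ``collapsed[t] == relative[t] + relative[revcomp(t)]``.
    """

    counts: dict[str, int]
    relative: dict[str, float]
    collapsed: dict[str, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trinucleotide": TRINUCLEOTIDES,
                "count": [self.counts[t] for t in TRINUCLEOTIDES],
                "relative_frequency": [self.relative[t] for t in TRINUCLEOTIDES],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def trinucleotide_composition(regions) -> TrinucleotideComposition:
    """Count trinucleotides over the interior positions of the region(s).

    Accepts a single :class:`ReferenceRegion` or an iterable of them (the
    multi-region case mirrors targeted panels whose composition baseline is
    pooled over all probes).  Each region contributes ``length - 2`` windows.
    """
    if isinstance(regions, ReferenceRegion):
        regions = [regions]
    regions = list(regions)
    counts = {t: 0 for t in TRINUCLEOTIDES}
    for region in regions:
        if region.length < 3:
            raise ValueError(
                f"region {region.name!r} is shorter than 3 nt ({region.length})"
            )
        s = region.sequence
        for i in range(1, region.length - 1):
            counts[s[i - 1 : i + 2]] += 1
    total = sum(counts.values())
    relative = {t: c / total for t, c in counts.items()}
    collapsed = {
        t: relative[t] + relative[revcomp(t)] for t in PYRIMIDINE_TRINUCLEOTIDES
    }
    return TrinucleotideComposition(counts=counts, relative=relative, collapsed=collapsed)


def extract_context(region: ReferenceRegion, pos: int, flank: int) -> str:
    """Return the ``2*flank + 1`` nt window centered on ``pos`` (0-based).

    Raises :class:`OutOfWindowError` when the window would run off either
    end; callers decide whether to skip the site.
    """
    if flank < 1:
        raise ValueError(f"flank must be >= 1, got {flank}")
    if pos - flank < 0 or pos + flank >= region.length:
        raise OutOfWindowError(
            f"window of flank {flank} around position {pos} exceeds "
            f"region {region.name!r} (length {region.length})"
        )
    return region.sequence[pos - flank : pos + flank + 1]
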
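"""96-channel trinucleotide mutational spectra.

A single-base substitution in its trinucleotide context is classified into
one of 96 channels written in pyrimidine-centered notation, e.g.
``A[C>T]G``: six substitution types (C>A, C>G, C>T, T>A, T>C, T>G) times 16
flanking-base combinations.  Purine-centered mutations are folded onto the
pyrimidine strand by reverse complement, so every raw (ref, alt, context)
triple maps onto exactly one channel and each channel collects exactly two
raw triples.

Spectra can be normalized against the trinucleotide composition of the
sequenced target (mutation frequency per trinucleotide) and compared by
cosine similarity, optionally after subtracting a background (vehicle
control) spectrum.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .refio import COMPLEMENT, TrinucleotideComposition, revcomp

SUBSTITUTION_TYPES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
#: Canonical channel order: substitution type major, then 5' base, then 3' base.
CHANNELS = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_TYPES
    for five in "ACGT"
    for three in "ACGT"
]
CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}


def parse_channel(channel: str) -> tuple[str, str, str, str]:
    """Split ``"A[C>T]G"`` into (five, ref, alt, three)."""
    if channel not in CHANNEL_INDEX:
        raise ValueError(f"unknown channel label {channel!r}")
    return channel[0], channel[2], channel[4], channel[6]


def channel_trinucleotide(channel: str) -> str:
    """Pyrimidine-centered reference trinucleotide of a channel."""
    five, ref, _alt, three = parse_channel(channel)
    return five + ref + three


def channel_of(ref: str, alt: str, context3: str) -> str:
    """Map a substitution plus reference trinucleotide onto its channel.

    ``context3`` is the reference trinucleotide with the mutated base at its
    center; purine-centered inputs are reverse-complemented onto the
    pyrimidine-centered channel.
    """
    if len(context3) != 3 or not set(context3) <= set("ACGT"):
        raise ValueError(f"invalid trinucleotide context {context3!r}")
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"invalid bases ref={ref!r} alt={alt!r}")
    if context3[1] != ref:
        raise ValueError(f"context {context3!r} center does not match ref {ref!r}")
    if alt == ref:
        raise ValueError("alt must differ from ref")
    if ref in "AG":
        context3 = revcomp(context3)
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{context3[0]}[{ref}>{alt}]{context3[2]}"


@dataclass
class Spectrum96:
    """Counts and/or frequencies over the 96 substitution channels.

    ``counts`` holds raw unique-mutation tallies; ``frequency`` holds a
    normalized (sum-1) vector.  Either may be absent; :attr:`vector` returns
    the frequency view, deriving it from counts on demand.
    """

    counts: np.ndarray | None = None
    frequency: np.ndarray | None = None
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.counts is None and self.frequency is None:
            self.counts = np.zeros(96)
        for attr in ("counts", "frequency"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (96,):
                    raise ValueError(f"{attr} must have 96 entries, got {v.shape}")
                if (v < 0).any():
                    raise ValueError(f"{attr} contains negative values")
                setattr(self, attr, v)
        if self.frequency is not None:
            total = self.frequency.sum()
            if total > 0 and abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequency must sum to 1, sums to {total!r}")

    @classmethod
    def from_counts(cls, counts, name: str = "", meta: dict | None = None) -> "Spectrum96":
        """Build from a channel->count mapping or a length-96 vector."""
        if isinstance(counts, dict):
            unknown = set(counts) - set(CHANNELS)
            if unknown:
                raise ValueError(f"unknown channel label(s) {sorted(unknown)!r}")
            vec = np.zeros(96)
            for ch, c in counts.items():
                vec[CHANNEL_INDEX[ch]] = c
        else:
            vec = np.asarray(counts, dtype=float)
        return cls(counts=vec, name=name, meta=meta or {})

    @classmethod
    def from_frequency(cls, freq, name: str = "", meta: dict | None = None) -> "Spectrum96":
        """Build from a channel->weight mapping or vector; renormalizes to 1."""
        if isinstance(freq, dict):
            unknown = set(freq) - set(CHANNELS)
            if unknown:
                raise ValueError(f"unknown channel label(s) {sorted(unknown)!r}")
            vec = np.zeros(96)
            for ch, f in freq.items():
                vec[CHANNEL_INDEX[ch]] = f
        else:
            vec = np.asarray(freq, dtype=float)
        total = vec.sum()
        if total <= 0:
            raise ValueError("frequency vector sums to zero")
        return cls(frequency=vec / total, name=name, meta=meta or {})

    @property
    def vector(self) -> np.ndarray:
        """Frequency view: explicit frequencies, else count proportions."""
        if self.frequency is not None:
            return self.frequency
        total = self.counts.sum()
        if total == 0:
            return np.zeros(96)
        return self.counts / total

    @property
    def total_count(self) -> float:
        return float(self.counts.sum()) if self.counts is not None else float("nan")

    def __getitem__(self, channel: str) -> float:
        return float(self.vector[CHANNEL_INDEX[channel]])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"channel": CHANNELS})
        if self.counts is not None:
            df["count"] = self.counts.astype(int)
        df["frequency"] = self.vector
        return df


def build_spectrum(mutations, name: str = "") -> Spectrum96:
    """Tally unique mutation calls into channel counts.

    Calls lacking a trinucleotide context (region-edge mutations) are
    excluded; the number excluded is recorded in ``meta['n_no_context']``
    and a warning is emitted if any were dropped.
    """
    counts = np.zeros(96)
    skipped = 0
    for m in mutations:
        if m.context3 is None:
            skipped += 1
            continue
        counts[CHANNEL_INDEX[channel_of(m.ref, m.alt, m.context3)]] += 1
    if skipped:
        warnings.warn(f"{skipped} mutation(s) without trinucleotide context excluded")
    return Spectrum96(counts=counts, name=name, meta={"n_no_context": skipped})


def normalize_spectrum(s: Spectrum96, comp: TrinucleotideComposition) -> Spectrum96:
    """Normalize channel proportions by the target's trinucleotide content.

    Each channel's share of the mutation total is divided by the
    strand-collapsed relative frequency of its reference trinucleotide in
    the sequenced target, then the vector is rescaled to sum to 1.  Channels
    whose trinucleotide never occurs in the target get frequency 0 and are
    listed in ``meta['channels_without_sites']``.
    """
    raw = s.vector.copy()
    if raw.sum() == 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    raw = raw / raw.sum()
    out = np.zeros(96)
    missing = []
    for i, ch in enumerate(CHANNELS):
        denom = comp.collapsed[channel_trinucleotide(ch)]
        if denom == 0:
            if raw[i] > 0:
                missing.append(ch)
            continue
        out[i] = raw[i] / denom
    if out.sum() == 0:
        raise ValueError("normalization produced an all-zero spectrum")
    meta = dict(s.meta)
    meta["channels_without_sites"] = missing
    return Spectrum96(counts=s.counts, frequency=out / out.sum(), name=s.name, meta=meta)


def subtract_background(s: Spectrum96, bg: Spectrum96, scale: float = 1.0) -> Spectrum96:
    """Subtract a background spectrum on the frequency scale, clamping at 0.

    ``max(0, s - scale*bg)`` per channel, then rescaled to sum to 1.  Both
    spectra should be normalized against the same target composition before
    subtraction.
    """
    diff = np.clip(s.vector - scale * bg.vector, 0.0, None)
    if diff.sum() == 0:
        raise ValueError("background subtraction left an all-zero spectrum")
    return Spectrum96(
        frequency=diff / diff.sum(),
        name=s.name,
        meta={**s.meta, "background": bg.name},
    )


def cosine_similarity(a, b) -> float:
    """Cosine similarity of two spectra (or raw 96-vectors); in [0, 1] for
    nonnegative inputs."""
    va = a.vector if isinstance(a, Spectrum96) else np.asarray(a, dtype=float)
    vb = b.vector if isinstance(b, Spectrum96) else np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(va, vb) / (na * nb))


@dataclass
class CosineMatrix:
    labels: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def similarity_matrix(
    spectra, signatures=(), background: Spectrum96 | None = None, scale: float = 1.0
) -> CosineMatrix:
    """All-against-all cosine matrix of sample spectra and signature vectors.

    When a ``background`` spectrum is given it is subtracted (clamped, then
    renormalized) from the sample spectra only — signature vectors are
    external references and enter the comparison untouched.
    """
    spectra = list(spectra)
    signatures = list(signatures)
    if len(spectra) + len(signatures) < 2:
        raise ValueError("need at least two spectra/signatures to compare")
    if background is not None:
        spectra = [subtract_background(s, background, scale=scale) for s in spectra]
    entries = spectra + signatures
    labels = [s.name or f"spectrum_{i}" for i, s in enumerate(entries)]
    n = len(entries)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = cosine_similarity(entries[i], entries[j])
    return CosineMatrix(labels=labels, values=values)


def average_spectra(spectra) -> Spectrum96:
    """Average per-sample spectra on the frequency scale.

    Each sample is first brought to its frequency view, then the mean
    vector is renormalized — i.e. samples are averaged after normalization,
    so a deeply sequenced animal does not dominate the cohort spectrum.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to average")
    mean = np.mean([s.vector for s in spectra], axis=0)
    if mean.sum() == 0:
        raise ValueError("all input spectra are zero")
    return Spectrum96(
        frequency=mean / mean.sum(),
        name="average",
        meta={"n_samples": len(spectra)},
    )


def write_spectrum(s: Spectrum96, path) -> None:
    """Write a spectrum as a TSV with columns channel[, count], frequency."""
    s.to_frame().to_csv(path, sep="\t", index=False)


def read_signature(path, name: str = "") -> Spectrum96:
    """Read a 96-row signature/spectrum TSV (columns ``channel``,
    ``frequency``; an optional ``count`` column is carried along).

    Rows may appear in any order and are reordered canonically.  Frequencies
    off from sum 1 by more than 1e-6 are renormalized with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    if "channel" not in df.columns or "frequency" not in df.columns:
        raise ValueError("signature TSV needs 'channel' and 'frequency' columns")
    if len(df) != 96:
        raise ValueError(f"signature TSV must have 96 rows, found {len(df)}")
    labels = list(df["channel"])
    unknown = set(labels) - set(CHANNELS)
    if unknown:
        raise ValueError(f"unknown channel label(s) {sorted(unknown)!r}")
    if len(set(labels)) != 96:
        raise ValueError("duplicate channel labels in signature TSV")
    df = df.set_index("channel").reindex(CHANNELS)
    freq = df["frequency"].to_numpy(dtype=float)
    if (freq < 0).any():
        raise ValueError("negative frequency in signature TSV")
    total = freq.sum()
    if total <= 0:
        raise ValueError("signature frequencies sum to zero")
    if abs(total - 1.0) > 1e-6:
        warnings.warn(f"signature frequencies sum to {total:.8f}; renormalizing")
    counts = df["count"].to_numpy(dtype=float) if "count" in df.columns else None
    return Spectrum96(counts=counts, frequency=freq / total, name=name or str(path))


# ---------------------------------------------------------------------------
# display helpers

_TYPE_COLORS = {
    "C>A": "#03bcee", "C>G": "#010101", "C>T": "#e32926",
    "T>A": "#cac9c9", "T>C": "#a1ce63", "T>G": "#ebc6c4",
}


def purine_label(channel: str) -> str:
    """Purine-centered display label, e.g. ``A[C>T]G`` -> ``C[G>A]T``."""
    five, ref, alt, three = parse_channel(channel)
    return (
        f"{COMPLEMENT[three]}[{COMPLEMENT[ref]}>{COMPLEMENT[alt]}]{COMPLEMENT[five]}"
    )


def plot_spectrum(s: Spectrum96, path, purine_labels: bool = False, title: str | None = None):
    """Render the 96-channel bar plot (one color block per substitution type)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(14, 3.2))
    vec = s.vector
    colors = [_TYPE_COLORS[f"{c[2]}>{c[4]}"] for c in CHANNELS]
    ax.bar(range(96), vec, color=colors)
    labels = [purine_label(c) if purine_labels else c for c in CHANNELS]
    ax.set_xticks(range(96))
    ax.set_xticklabels(labels, rotation=90, fontsize=4)
    ax.set_ylabel("frequency")
    ax.set_title(title or s.name)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
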
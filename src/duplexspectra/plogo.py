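"""Probability-logo (pLOGO-style) statistics.

For a set of fixed-base-centered sequence windows (foreground, e.g. the
15-mers around every unique G>A mutation) the over- or under-representation
of each base at each flanking position is scored against a background
window set by a signed log-odds of the exact binomial tail probability:

* overrepresentation (k/n > p):  ``P = Pr[X >= k]``, height ``+log10((1-P)/P)``
* underrepresentation (k/n < p): ``P = Pr[X <= k]``, height ``-log10((1-P)/P)``

with ``k`` the foreground count of the base at that position, ``n`` the
foreground size, and ``p`` the background frequency.  Tails are exact sums
computed in log space (no normal approximation, no capping), so extreme
enrichments keep finite, meaningful heights.  Significance uses a
Bonferroni-corrected log-odds bound over all position x base cells; with
the defaults (14 flanking positions x 4 bases at alpha 0.05) the bound is
3.05.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .consensus import encode
from .refio import COMPLEMENT, ReferenceRegion, revcomp

_LN10 = math.log(10.0)
_BASES = "ACGT"


@dataclass
class ContextWindowSet:
    """Fixed-width windows sharing a center base (foreground or background)."""

    windows: list[str]
    role: str  # "foreground" | "background"
    center_base: str
    flank: int

    def __post_init__(self):
        w = 2 * self.flank + 1
        for win in self.windows:
            if len(win) != w:
                raise ValueError(f"window {win!r} is not {w} nt wide")
            if win[self.flank] != self.center_base:
                raise ValueError(
                    f"window {win!r} center is not {self.center_base!r}"
                )

    @property
    def n(self) -> int:
        return len(self.windows)

    def base_counts(self) -> np.ndarray:
        """(width, 4) counts of A,C,G,T at each window position."""
        width = 2 * self.flank + 1
        counts = np.zeros((width, 4), dtype=np.int64)
        if self.windows:
            arr = encode("".join(self.windows)).reshape(len(self.windows), width)
            for b in range(4):
                counts[:, b] = (arr == b).sum(axis=0)
        return counts


def extract_foreground_windows(
    mutations,
    region: ReferenceRegion,
    ref_base: str = "G",
    alt_base: str = "A",
    flank: int = 7,
) -> tuple[ContextWindowSet, int]:
    """Reference windows around every unique mutation of one substitution
    type, oriented so the center reads ``ref_base``.

    A mutation recorded on the opposite strand (e.g. C>T for a G>A
    analysis) contributes the reverse-complemented window.  Mutations
    closer than ``flank`` to a region end are skipped and counted.
    """
    comp_ref, comp_alt = COMPLEMENT[ref_base], COMPLEMENT[alt_base]
    windows = []
    skipped = 0
    for m in mutations:
        if (m.ref, m.alt) == (ref_base, alt_base):
            reverse = False
        elif (m.ref, m.alt) == (comp_ref, comp_alt):
            reverse = True
        else:
            continue
        if m.pos - flank < 0 or m.pos + flank >= region.length:
            skipped += 1
            continue
        w = region.sequence[m.pos - flank : m.pos + flank + 1]
        windows.append(revcomp(w) if reverse else w)
    return (
        ContextWindowSet(windows=windows, role="foreground", center_base=ref_base, flank=flank),
        skipped,
    )


def extract_background_windows(
    regions,
    ref_base: str = "G",
    flank: int = 7,
    sample_size: int | None = None,
    seed: int | None = None,
) -> ContextWindowSet:
    """All (or a seeded uniform subsample of) windows centered on the fixed
    base across both strands of the region(s), orientation-normalized as in
    the foreground."""
    if isinstance(regions, ReferenceRegion):
        regions = [regions]
    comp_base = COMPLEMENT[ref_base]
    windows: list[str] = []
    for region in regions:
        seq = region.sequence
        for pos in range(flank, region.length - flank):
            if seq[pos] == ref_base:
                windows.append(seq[pos - flank : pos + flank + 1])
            elif seq[pos] == comp_base:
                windows.append(revcomp(seq[pos - flank : pos + flank + 1]))
    if not windows:
        raise ValueError(f"no occurrences of center base {ref_base!r} in region(s)")
    if sample_size is not None:
        if sample_size > len(windows):
            raise ValueError(
                f"sample_size {sample_size} exceeds available {len(windows)} windows"
            )
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(windows), size=sample_size, replace=False)
        windows = [windows[i] for i in sorted(idx)]
    return ContextWindowSet(windows=windows, role="background", center_base=ref_base, flank=flank)


def _log_binom_tail(k_lo: int, k_hi: int, n: int, p: float) -> float:
    """log Pr[k_lo <= X <= k_hi] for X ~ Binomial(n, p), exact in log space."""
    if k_lo > k_hi:
        return -math.inf
    i = np.arange(k_lo, k_hi + 1, dtype=np.float64)
    log_terms = (
        gammaln(n + 1)
        - gammaln(i + 1)
        - gammaln(n - i + 1)
        + i * math.log(p)
        + (n - i) * math.log1p(-p)
    )
    return float(logsumexp(log_terms))


def binomial_logodds(k: int, n: int, p: float) -> float:
    """Signed log-odds of the exact binomial tail probability.

    Positive when the observed fraction ``k/n`` exceeds the background
    probability ``p``, negative when below, 0 at the boundary.  Both the
    tail and its complement are computed by direct log-space summation, so
    the result stays accurate even when one side underflows a double.
    """
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"background probability must be in (0, 1), got {p}")
    if k == n * p:
        return 0.0
    if k > n * p:  # overrepresented: P = Pr[X >= k]
        log_p_tail = _log_binom_tail(k, n, n, p)
        log_complement = _log_binom_tail(0, k - 1, n, p)
        return (log_complement - log_p_tail) / _LN10
    # underrepresented: P = Pr[X <= k]
    log_p_tail = _log_binom_tail(0, k, n, p)
    log_complement = _log_binom_tail(k + 1, n, n, p)
    return -(log_complement - log_p_tail) / _LN10


def bonferroni_threshold(
    alpha: float = 0.05, n_positions: int = 14, n_bases: int = 4
) -> float:
    """Bonferroni-corrected significance bound on the log-odds scale.

    ``alpha' = alpha / (n_positions * n_bases)``; the bound is
    ``log10((1 - alpha') / alpha')``.  With the defaults (56 tests) this is
    3.05 to two decimals.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    m = n_positions * n_bases
    if m < 1:
        raise ValueError("need at least one test")
    a = alpha / m
    return math.log10((1 - a) / a)


@dataclass
class PLogoResult:
    """Per position x base log-odds heights with supporting counts."""

    positions: list[int]  # -flank..-1, 1..flank (center excluded)
    bases: str
    heights: np.ndarray       # (n_positions, 4)
    k: np.ndarray             # foreground counts, same shape
    p: np.ndarray             # background frequencies, same shape
    n_fg: int
    n_bg: int
    threshold: float
    alpha: float

    @property
    def significant(self) -> np.ndarray:
        return np.abs(self.heights) >= self.threshold

    def height(self, position: int, base: str) -> float:
        return float(self.heights[self.positions.index(position), self.bases.index(base)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, pos in enumerate(self.positions):
            for j, base in enumerate(self.bases):
                rows.append(
                    {
                        "position": pos,
                        "base": base,
                        "k": int(self.k[i, j]),
                        "n": self.n_fg,
                        "p": self.p[i, j],
                        "frequency_pct": 100.0 * self.k[i, j] / self.n_fg,
                        "height": self.heights[i, j],
                        "significant": bool(self.significant[i, j]),
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def plogo_matrix(
    fg: ContextWindowSet, bg: ContextWindowSet, alpha: float = 0.05
) -> PLogoResult:
    """Score every flanking position x base cell of the foreground against
    the background.

    A background frequency of exactly 0 where the foreground has counts is
    floored at ``1/(n_bg + 1)`` with a warning (avoids infinite heights on
    small backgrounds); a frequency of 1 is ceiled symmetrically.
    """
    if fg.flank != bg.flank or fg.center_base != bg.center_base:
        raise ValueError("foreground and background windows are incompatible")
    if fg.n == 0 or bg.n == 0:
        raise ValueError("empty window set")
    width = 2 * fg.flank + 1
    fg_counts = fg.base_counts()
    bg_freq = bg.base_counts() / bg.n
    positions = [j - fg.flank for j in range(width) if j != fg.flank]
    rows = [j for j in range(width) if j != fg.flank]
    heights = np.zeros((len(rows), 4))
    kmat = np.zeros((len(rows), 4), dtype=np.int64)
    pmat = np.zeros((len(rows), 4))
    floor = 1.0 / (bg.n + 1)
    for out_i, j in enumerate(rows):
        for b in range(4):
            k = int(fg_counts[j, b])
            p = float(bg_freq[j, b])
            if p == 0.0:
                if k > 0:
                    warnings.warn(
                        f"background frequency 0 for {_BASES[b]} at position "
                        f"{positions[out_i]}; flooring at 1/(n_bg+1)"
                    )
                p = floor
            elif p == 1.0:
                p = 1.0 - floor
            kmat[out_i, b] = k
            pmat[out_i, b] = p
            heights[out_i, b] = binomial_logodds(k, fg.n, p)
    threshold = bonferroni_threshold(alpha, n_positions=len(rows), n_bases=4)
    return PLogoResult(
        positions=positions,
        bases=_BASES,
        heights=heights,
        k=kmat,
        p=pmat,
        n_fg=fg.n,
        n_bg=bg.n,
        threshold=threshold,
        alpha=alpha,
    )


def plot_logo(result: PLogoResult, path, title: str | None = None) -> None:
    """Render a simple letter-height logo of the log-odds matrix.

    At each flanking position the bases are stacked in height order above
    (positive) and below (negative) the axis; red lines mark the Bonferroni
    bound.  This is a plain matplotlib rendering, adequate for inspection.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    fig, ax = plt.subplots(figsize=(10, 4))
    for i, pos in enumerate(result.positions):
        ups = sorted(
            [(result.heights[i, b], result.bases[b]) for b in range(4) if result.heights[i, b] > 0]
        )
        downs = sorted(
            [(result.heights[i, b], result.bases[b]) for b in range(4) if result.heights[i, b] < 0],
            reverse=True,
        )
        y = 0.0
        for h, base in ups:
            ax.bar(pos, h, bottom=y, width=0.8, color=colors[base], alpha=0.35)
            ax.text(pos, y + h / 2, base, ha="center", va="center", fontsize=7)
            y += h
        y = 0.0
        for h, base in downs:
            ax.bar(pos, h, bottom=y, width=0.8, color=colors[base], alpha=0.35)
            ax.text(pos, y + h / 2, base, ha="center", va="center", fontsize=7)
            y += h
    ax.axhline(result.threshold, color="red", lw=1)
    ax.axhline(-result.threshold, color="red", lw=1)
    ax.axhline(0, color="black", lw=0.8)
    ax.set_xlabel("position relative to the fixed center base")
    ax.set_ylabel("log-odds")
    ax.set_title(title or f"n(fg)={result.n_fg}, n(bg)={result.n_bg}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
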
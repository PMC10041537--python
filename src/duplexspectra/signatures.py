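"""Synthetic signature fixtures.

These spectra are constructed look-alikes used by the simulator and the test
suite; they are *not* COSMIC data (real signature vectors are user-supplied
TSV inputs).  Two shapes are provided:

* :func:`sbs11_like` — an alkylation-style spectrum dominated by C>T on the
  pyrimidine strand with a 3' C or T neighbor.  On the purine strand this is
  G>A with a 5' purine, i.e. the 5'-Pu-G-3' context preference of
  O6-methylguanine-driven mutagenesis, plus a small T>C (A:T->G:C) component
  and a diffuse transversion floor.
* :func:`cpg_control` — a deamination-style vehicle-control spectrum with
  C>T concentrated at CpG sites (3' G neighbor) over a flat background, the
  classic 5-methylcytosine deamination pattern.
"""
from __future__ import annotations

import numpy as np

from .spectrum import CHANNELS, Spectrum96, parse_channel

# Mild 5'-neighbor variation so the fixture spectra are rugged rather than
# blockily uniform, as real spectra are.
_FIVE_WEIGHT = {"A": 1.1, "C": 0.9, "G": 1.2, "T": 0.8}


def sbs11_like() -> Spectrum96:
    """Synthetic alkylation (SBS11-like) spectrum: 5'-Pu-G enriched GC->AT."""
    three_weight = {"C": 5.0, "T": 3.6, "A": 0.45, "G": 0.35}
    weights = np.zeros(96)
    for i, ch in enumerate(CHANNELS):
        five, ref, alt, three = parse_channel(ch)
        sub = f"{ref}>{alt}"
        if sub == "C>T":
            weights[i] = 2.0 * three_weight[three] * _FIVE_WEIGHT[five]
        elif sub == "T>C":
            weights[i] = 0.55
        else:
            weights[i] = 0.12
    return Spectrum96.from_frequency(weights, name="synthetic-SBS11-like")


def cpg_control() -> Spectrum96:
    """Synthetic vehicle-control spectrum: C>T at CpG over a flat background."""
    weights = np.zeros(96)
    for i, ch in enumerate(CHANNELS):
        five, ref, alt, three = parse_channel(ch)
        if f"{ref}>{alt}" == "C>T" and three == "G":
            weights[i] = 8.0 * _FIVE_WEIGHT[five]
        else:
            weights[i] = 0.35
    return Spectrum96.from_frequency(weights, name="synthetic-CpG-control")


def pug_ct_only() -> Spectrum96:
    """Pure 5'-Pu-G spectrum: all mass on C>T channels with 3' C or T.

    Used to probe context-enrichment recovery — every injected mutation is a
    G>A with a purine 5' of the G on the purine strand.
    """
    weights = np.zeros(96)
    for i, ch in enumerate(CHANNELS):
        _five, ref, alt, three = parse_channel(ch)
        if f"{ref}>{alt}" == "C>T" and three in "CT":
            weights[i] = 1.0
    return Spectrum96.from_frequency(weights, name="synthetic-PuG-only")
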
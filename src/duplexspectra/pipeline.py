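"""End-to-end pipeline orchestration.

Stage order mirrors the experimental data flow: (optional) simulation ->
duplex consensus -> placement & mutation calling -> spectrum construction
and normalization -> signature comparison -> context-enrichment (pLOGO).
Every stage writes plain-text artifacts into the output directory and
records its filtering counters in a run manifest, so a run is resumable
from its on-disk intermediates and every discarded read is attributed to
exactly one counter.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import consensus, duplexsim, mutcall, plogo, refio, signatures, spectrum


def parse_trim_ranges(text: str) -> tuple[tuple[int, int], ...]:
    """Parse a trim specification like ``"1-8,120-137"`` (1-based inclusive).

    An empty string means no trimming.
    """
    text = text.strip()
    if not text:
        return ()
    out = []
    for part in text.split(","):
        lo, hi = part.split("-")
        out.append((int(lo), int(hi)))
    return tuple(out)


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults follow the documented stage
    defaults (trim 1-8 and 120-137, 300-350 bp fragments, flank 7,
    alpha 0.05, min family size 3, consensus threshold 0.7)."""

    outdir: str = "duplexspectra_run"
    # inputs (optional: simulated when absent)
    reference_fasta: str | None = None
    reads_r1: str | None = None
    reads_r2: str | None = None
    signature_tsv: str | None = None
    # simulation
    sim_spectrum: str = "sbs11_like"  # sbs11_like | cpg_control | pug_ct_only
    n_molecules: int = 1000
    mutation_rate: float = 1e-4
    fragment_min: int = 300
    fragment_max: int = 350
    read_length: int = 137
    family_size_mean: float = 5.0
    family_size_min: int = 0
    per_base_error_rate: float = 1e-3
    tag_length: int = 12
    # consensus
    min_family_size: int = 3
    consensus_threshold: float = 0.7
    trim: str = "1-8,120-137"
    reject_on_disagreement: bool = False
    # calling
    seed_length: int = 20
    min_identity: float = 0.9
    dedup_by_position: bool = False
    # plogo
    plogo_ref_base: str = "G"
    plogo_alt_base: str = "A"
    plogo_flank: int = 7
    plogo_alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        parse_trim_ranges(self.trim)
        if self.sim_spectrum not in ("sbs11_like", "cpg_control", "pug_ct_only"):
            raise ValueError(f"unknown sim_spectrum {self.sim_spectrum!r}")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if self.plogo_ref_base not in "ACGT" or self.plogo_alt_base not in "ACGT":
            raise ValueError("plogo bases must be A/C/G/T")

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in asdict(self).items():
                fh.write(f"{k} = {v if v is not None else ''}\n")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        values: dict = {}
        types = {f.name: f.type for f in cls.__dataclass_fields__.values()}  # noqa: F841
        defaults = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key not in cls.__dataclass_fields__:
                    raise ValueError(f"unknown config key {key!r}")
                default = getattr(defaults, key)
                if raw == "" or raw == "None":
                    values[key] = None if key.endswith(("_fasta", "_r1", "_r2", "_tsv")) else default
                elif isinstance(default, bool):
                    values[key] = raw.lower() in ("1", "true", "yes")
                elif isinstance(default, int):
                    values[key] = int(raw)
                elif isinstance(default, float):
                    values[key] = float(raw)
                else:
                    values[key] = raw
        values.update(overrides)
        return cls(**values)


_SIM_SPECTRA = {
    "sbs11_like": signatures.sbs11_like,
    "cpg_control": signatures.cpg_control,
    "pug_ct_only": signatures.pug_ct_only,
}


def simulate_and_recover(
    region,
    sim_spectrum,
    n_molecules: int,
    mutation_rate: float,
    seed: int,
    per_base_error_rate: float = 1e-3,
    min_family_size: int = 3,
    workdir=None,
    site_index=None,
):
    """One synthetic sample end to end: simulate reads, run duplex
    consensus, place and call, return ``(unique_mutations, reports)``.

    Intermediate FASTQ/truth files go to ``workdir`` (a temporary directory
    when omitted).
    """
    import tempfile

    cfg = duplexsim.SimulationConfig(
        spectrum=sim_spectrum,
        n_molecules=n_molecules,
        mutation_rate=mutation_rate,
        per_base_error_rate=per_base_error_rate,
        seed=seed,
    )
    with tempfile.TemporaryDirectory() as tmp:
        d = Path(workdir) if workdir is not None else Path(tmp)
        d.mkdir(parents=True, exist_ok=True)
        r1, r2 = d / "reads_R1.fastq", d / "reads_R2.fastq"
        molecules = duplexsim.simulate_molecules(cfg, region, site_index)
        sim_stats = duplexsim.simulate_reads(
            molecules, region, cfg, r1, r2, d / "truth.tsv"
        )
        dcs_reads, cons_report = consensus.run_consensus(
            r1, r2, min_family_size=min_family_size
        )
    uniq, _calls, call_report = mutcall.place_and_call(dcs_reads, region)
    truth = sim_stats["truth"]
    return uniq, {"simulate": sim_stats, "consensus": cons_report,
                  "call": call_report, "truth": truth}


def run_synthetic_cohort(
    region,
    sim_spectrum,
    n_animals: int,
    n_molecules: int,
    mutation_rate: float,
    seed: int,
    **kwargs,
):
    """Simulate a cohort of animals and build the cohort spectrum.

    Each animal is an independent simulation (seeds derived from ``seed``);
    unique mutations are collapsed per animal, pooled across the cohort
    with inter-individual replicates retained, and per-animal normalized
    spectra are averaged on the frequency scale.  Returns
    ``(pooled_mutations, average_normalized_spectrum, per_animal_uniques)``.
    """
    comp = refio.trinucleotide_composition(region)
    site_index = duplexsim.ChannelSiteIndex(region)
    pooled = []
    per_animal = []
    normalized = []
    for animal in range(n_animals):
        uniq, _reports = simulate_and_recover(
            region,
            sim_spectrum,
            n_molecules=n_molecules,
            mutation_rate=mutation_rate,
            seed=seed * 1000 + animal,
            site_index=site_index,
            **kwargs,
        )
        per_animal.append(uniq)
        pooled.extend(uniq)
        spec = spectrum.build_spectrum(uniq, name=f"animal_{animal}")
        if spec.counts.sum() > 0:
            normalized.append(spectrum.normalize_spectrum(spec, comp))
    avg = spectrum.average_spectra(normalized) if normalized else None
    return pooled, avg, per_animal


def run_pipeline(config: PipelineConfig, resume: bool = False) -> Path:
    """Execute all stages; returns the output directory.

    With ``resume=True`` a stage whose primary artifact already exists is
    skipped and its output re-read, so a rerun after an interruption (or a
    parameter-only change downstream) reuses intermediates.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_file(out / "config.used")
    manifest: dict = {"seed": config.seed, "stages": []}

    # --- reference -------------------------------------------------------
    if config.reference_fasta:
        regions = refio.load_reference(config.reference_fasta)
    else:
        regions = [duplexsim.synthetic_reference(seed=config.seed)]
        ref_path = out / "reference.synthetic.fasta"
        if not (resume and ref_path.exists()):
            with open(ref_path, "w") as fh:
                fh.write(f">{regions[0].name}\n{regions[0].sequence}\n")
    region = regions[0]
    comp = refio.trinucleotide_composition(regions)
    comp.to_tsv(out / "composition.tsv")

    # --- simulate --------------------------------------------------------
    r1, r2 = config.reads_r1, config.reads_r2
    truth_path = out / "truth.tsv"
    if r1 is None:
        r1, r2 = out / "reads_R1.fastq", out / "reads_R2.fastq"
        if not (resume and Path(r1).exists()):
            sim_cfg = duplexsim.SimulationConfig(
                spectrum=_SIM_SPECTRA[config.sim_spectrum](),
                n_molecules=config.n_molecules,
                mutation_rate=config.mutation_rate,
                fragment_length_range=(config.fragment_min, config.fragment_max),
                read_length=config.read_length,
                family_size_mean=config.family_size_mean,
                family_size_min=config.family_size_min,
                per_base_error_rate=config.per_base_error_rate,
                tag_length=config.tag_length,
                seed=config.seed,
            )
            molecules = duplexsim.simulate_molecules(sim_cfg, region)
            sim_stats = duplexsim.simulate_reads(
                molecules, region, sim_cfg, r1, r2, truth_path
            )
            manifest["stages"].append(
                {
                    "stage": "simulate",
                    "n_molecules": sim_stats["n_molecules"],
                    "n_read_pairs": sim_stats["n_read_pairs"],
                }
            )

    # --- consensus -------------------------------------------------------
    dcs_path = out / "dcs.fastq"
    dcs_reads, report = consensus.run_consensus(
        r1,
        r2,
        tag_length=config.tag_length,
        min_family_size=config.min_family_size,
        consensus_threshold=config.consensus_threshold,
        trim_ranges=parse_trim_ranges(config.trim),
        reject_on_disagreement=config.reject_on_disagreement,
    )
    consensus.write_dcs_fastq(dcs_reads, dcs_path)
    manifest["stages"].append({"stage": "consensus", **report})

    # --- call ------------------------------------------------------------
    uniq, calls, call_report = mutcall.place_and_call(
        dcs_reads,
        regions,
        seed_length=config.seed_length,
        min_identity=config.min_identity,
        by_position=config.dedup_by_position,
    )
    mutcall.mutations_to_tsv(calls, out / "mutations.tsv")
    mutcall.mutations_to_tsv(uniq, out / "unique_mutations.tsv")
    mutcall.mutations_to_vcf(uniq, out / "unique_mutations.vcf")
    manifest["stages"].append({"stage": "call", **call_report})

    # --- spectrum --------------------------------------------------------
    spec = spectrum.build_spectrum(uniq, name="sample")
    spectrum.write_spectrum(spec, out / "spectrum.tsv")
    if spec.counts.sum() > 0:
        norm = spectrum.normalize_spectrum(spec, comp)
        spectrum.write_spectrum(norm, out / "spectrum_normalized.tsv")
        spectrum.plot_spectrum(norm, out / "spectrum_normalized.png")
    else:
        norm = None
    manifest["stages"].append(
        {"stage": "spectrum", "total_mutations": int(spec.counts.sum())}
    )

    # --- compare ---------------------------------------------------------
    if config.signature_tsv and norm is not None:
        sig = spectrum.read_signature(config.signature_tsv)
        matrix = spectrum.similarity_matrix([norm], [sig])
        matrix.to_tsv(out / "cosine_matrix.tsv")
        manifest["stages"].append(
            {"stage": "compare", "cosine": float(matrix.values[0, 1])}
        )

    # --- plogo -----------------------------------------------------------
    fg, skipped = plogo.extract_foreground_windows(
        uniq,
        region,
        ref_base=config.plogo_ref_base,
        alt_base=config.plogo_alt_base,
        flank=config.plogo_flank,
    )
    if fg.n > 0:
        bg = plogo.extract_background_windows(
            regions, ref_base=config.plogo_ref_base, flank=config.plogo_flank
        )
        result = plogo.plogo_matrix(fg, bg, alpha=config.plogo_alpha)
        result.to_tsv(out / "plogo.tsv")
        plogo.plot_logo(result, out / "plogo.png")
        manifest["stages"].append(
            {
                "stage": "plogo",
                "n_fg": fg.n,
                "n_bg": bg.n,
                "n_skipped_edge": skipped,
                "threshold": result.threshold,
            }
        )

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
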
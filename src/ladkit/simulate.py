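"""Seeded synthetic data with known truth for every pipeline stage.

The generators emulate the structure of the study's inputs at a
mouse-like scale-down so every stage runs and is verified without the
deposited datasets:

* a random genome with GATC motifs placed as a Poisson process
  (~4 motifs/kb, i.e. ~250 bp DpnI fragments, matching the genome-wide GATC
  density), with accidental background motifs detected and included in the
  truth;
* planted LADs (non-overlapping, 100–500 kb, minimum spacing) and per-GATC-
  fragment DamID read counts: Dam-only at a flat mean depth, Dam-fusion
  elevated ``fold_enrichment``-fold inside the planted domains, with Poisson
  or negative-binomial count noise;
* biotinylation-site tables with a planted enriched protein subset at a
  stated fold change under multiplicative log-normal abundance noise across
  duplicate replicates, plus the matching proteome FASTA;
* peak sets constructed to hit a target base/midpoint overlap with a region
  set.

Every generator is a pure function of (config, seed): regeneration is
byte-identical. What the generators do NOT emulate: mappability structure,
PCR amplification bias, read-level base-call errors, peptide-level missing
data patterns — see the methods note for the implications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .damid import BinCounts, LadSet
from .gatc import GatcFragmentMap, GenomeSequence
from .intervals import IntervalSet

__all__ = [
    "SimulationConfig",
    "simulate_genome",
    "plant_lads",
    "simulate_damid_counts",
    "simulate_biosite_table",
    "simulate_peaks",
]


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic pipeline.

    The defaults mirror the scaled-down study conditions: one 10 Mb
    chromosome, GATC every ~250 bp, 15 planted LADs of 100–500 kb spaced
    >= 50 kb apart, Poisson counts at mean depth 10 reads/fragment with
    4-fold Dam-fusion enrichment inside LADs; 500 proteins with 50 planted
    3-fold enriched under log-normal noise (sd 0.2 in ln space) across 2
    replicates; 500 peaks targeting 80% midpoint overlap.
    """

    seed: int = 0
    # genome
    genome_length: int = 10_000_000
    gatc_rate: float = 4.0            # expected motifs per kb
    chrom: str = "chrSim"
    # planted LADs
    n_lads: int = 15
    lad_size_range: tuple[int, int] = (100_000, 500_000)
    lad_min_spacing: int = 50_000
    # DamID counts
    mean_depth: float = 10.0          # reads per fragment
    fold_enrichment: float = 4.0
    noise: str = "poisson"            # or "negative_binomial"
    nb_dispersion: float = 2.0
    # biotinylation sites
    n_proteins: int = 500
    n_enriched: int = 50
    biosite_fold: float = 3.0
    lognormal_sd: float = 0.2
    n_replicates: int = 2
    sites_per_protein: tuple[int, int] = (1, 5)
    protein_length_range: tuple[int, int] = (200, 800)
    conditions: tuple[str, str] = ("bait", "control")
    # peaks
    n_peaks: int = 500
    peak_width_range: tuple[int, int] = (200, 2_000)
    target_overlap_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.fold_enrichment < 1:
            raise ValueError("fold_enrichment must be >= 1")
        if not (0 <= self.target_overlap_fraction <= 1):
            raise ValueError("target_overlap_fraction must be in [0, 1]")
        for lo, hi in (self.lad_size_range, self.sites_per_protein,
                       self.peak_width_range, self.protein_length_range):
            if lo > hi:
                raise ValueError("range min must be <= max")
        if self.n_enriched > self.n_proteins:
            raise ValueError("n_enriched must be <= n_proteins")


_BASES = np.array(list("ACGT"))


def simulate_genome(config: SimulationConfig) -> tuple[GenomeSequence, list[int]]:
    """Random genome with GATC motifs inserted as a Poisson process.

    Returns the genome and the complete, sorted truth list of GATC start
    positions — inserted motifs plus any accidental background occurrences
    (detected by rescanning, so the truth is exact).
    """
    if config.genome_length < 1_000:
        raise ValueError("genome_length must be >= 1 kb")
    mean_gap = 1_000.0 / config.gatc_rate if config.gatc_rate > 0 else np.inf
    if config.gatc_rate > 0 and mean_gap < 8:
        raise ValueError("gatc_rate too high: motifs would overlap")
    rng = np.random.default_rng(config.seed)
    seq = rng.choice(_BASES, size=config.genome_length)
    # ablate accidental background GATCs (A -> C cannot create a new motif)
    # so the realised motif density matches gatc_rate, then insert motifs as
    # a Poisson process; a final exact rescan defines the truth either way.
    from .gatc import scan_gatc_sites

    for p in scan_gatc_sites("".join(seq)):
        seq[p + 1] = "C"
    if config.gatc_rate > 0:
        n_target = rng.poisson(config.gatc_rate * config.genome_length / 1_000)
        starts = np.sort(rng.choice(config.genome_length - 4, size=n_target, replace=False))
        # drop insertions that would overlap a previous one
        keep = np.concatenate([[True], np.diff(starts) >= 4]) if starts.size else np.array([], bool)
        for p in starts[keep]:
            seq[p:p + 4] = list("GATC")
    genome = GenomeSequence(config.chrom, "".join(seq))
    return genome, scan_gatc_sites(genome.seq)


def plant_lads(config: SimulationConfig) -> LadSet:
    """Non-overlapping truth LADs with sizes uniform in the configured range
    and spacing >= the configured minimum."""
    lo, hi = config.lad_size_range
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sizes = rng.integers(lo, hi + 1, size=config.n_lads)
    spacing = config.lad_min_spacing
    occupied = int(sizes.sum()) + spacing * (config.n_lads + 1)
    free = config.genome_length - occupied
    if free < 0:
        raise ValueError(
            f"cannot place {config.n_lads} LADs of {lo}-{hi} bp with {spacing} bp "
            f"spacing in {config.genome_length} bp; reduce n_lads or sizes"
        )
    # distribute the free space over the n+1 gaps uniformly
    extra = rng.multinomial(free, np.full(config.n_lads + 1, 1 / (config.n_lads + 1)))
    gaps = spacing + extra
    intervals = []
    pos = 0
    for k in range(config.n_lads):
        pos += int(gaps[k])
        intervals.append((pos, pos + int(sizes[k])))
        pos += int(sizes[k])
    out = LadSet()
    out.intervals[config.chrom] = np.asarray(intervals, dtype=np.int64)
    return out


def simulate_damid_counts(
    frags: GatcFragmentMap, truth: LadSet, config: SimulationConfig
) -> tuple[BinCounts, BinCounts]:
    """Per-fragment (fusion, control) counts with planted LAD enrichment.

    Control mean = ``mean_depth`` everywhere; fusion mean = depth · fold
    inside truth LADs (fragment assigned by midpoint), depth outside.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    mids = frags.fragments.sum(axis=1) // 2
    truth_iv = IntervalSet({frags.chrom: truth.intervals.get(frags.chrom, np.zeros((0, 2), np.int64))})
    inside = truth_iv.contains_points(frags.chrom, mids)
    mu_control = np.full(frags.n_fragments, config.mean_depth)
    mu_fusion = np.where(inside, config.mean_depth * config.fold_enrichment, config.mean_depth)

    def draw(mu):
        if config.noise == "poisson":
            return rng.poisson(mu)
        if config.noise == "negative_binomial":
            # NB with mean mu, variance mu * dispersion (dispersion > 1)
            d = config.nb_dispersion
            if d <= 1:
                raise ValueError("nb_dispersion must be > 1")
            p = 1.0 / d
            r = mu * p / (1 - p)
            return rng.negative_binomial(r, p)
        raise ValueError(f"unknown noise model {config.noise!r}")

    fusion = draw(mu_fusion)
    control = draw(mu_control)
    return (
        BinCounts(frags, fusion, int(fusion.sum())),
        BinCounts(frags, control, int(control.sum())),
    )


_AA_POOL = np.array(list("ARNDCEQGHILMFPSTWYV"))  # K added separately


def simulate_biosite_table(config: SimulationConfig) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Biotinylation-site table with a planted enriched subset.

    Returns (site table, proteome {id: sequence}, truth labels). Protein
    sequences carry enough lysines for the requested sites; baseline
    abundances are log-normal; the first ``n_enriched`` proteins are
    multiplied by ``biosite_fold`` in the numerator condition; replicates
    share the condition mean with independent multiplicative log-normal
    noise (sd ``lognormal_sd`` in ln space).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    num_cond, den_cond = config.conditions
    rows = []
    proteome: dict[str, str] = {}
    truth_rows = []
    for i in range(config.n_proteins):
        pid = f"PROT{i:04d}"
        enriched = i < config.n_enriched
        length = int(rng.integers(*config.protein_length_range))
        n_sites = int(rng.integers(config.sites_per_protein[0],
                                   config.sites_per_protein[1] + 1))
        # sequence with lysines sprinkled in (~8% K, at least n_sites)
        seq = rng.choice(_AA_POOL, size=length)
        n_k = max(n_sites, int(round(0.08 * length)))
        k_pos = rng.choice(length, size=n_k, replace=False)
        seq[k_pos] = "K"
        proteome[pid] = "".join(seq)
        site_positions = np.sort(rng.choice(k_pos, size=n_sites, replace=False)) + 1
        base = float(rng.lognormal(mean=np.log(1e6), sigma=1.0))
        for pos in site_positions:
            site_base = base * float(rng.lognormal(0, 0.5))
            for cond in config.conditions:
                mu = site_base * (config.biosite_fold if (enriched and cond == num_cond) else 1.0)
                for rep in range(1, config.n_replicates + 1):
                    rows.append({
                        "protein_id": pid,
                        "site_pos": int(pos),
                        "residue": "K",
                        "condition": cond,
                        "replicate": rep,
                        "abundance": mu * float(rng.lognormal(0, config.lognormal_sd)),
                    })
        truth_rows.append({"protein_id": pid, "enriched": enriched})
    return pd.DataFrame(rows), proteome, pd.DataFrame(truth_rows)


def simulate_peaks(
    regions: IntervalSet, config: SimulationConfig
) -> tuple[IntervalSet, float]:
    """Peak set hitting a target midpoint-overlap fraction with ``regions``.

    Each peak's midpoint is placed inside the regions with probability
    ``target_overlap_fraction`` and outside otherwise; returns the peaks and
    the achieved fraction.
    """
    if not regions.intervals:
        raise ValueError("regions must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    chrom = sorted(regions.intervals)[0]
    reg = regions.intervals[chrom]
    L = config.genome_length
    # complement of regions within [0, L)
    comp = []
    prev = 0
    for s, e in reg:
        if s > prev:
            comp.append((prev, s))
        prev = e
    if prev < L:
        comp.append((prev, L))
    comp = np.asarray(comp, dtype=np.int64).reshape(-1, 2)
    if config.target_overlap_fraction < 1 and comp.size == 0:
        raise ValueError("no space outside regions to place non-overlapping peaks")

    def sample_point(iv):
        lens = iv[:, 1] - iv[:, 0]
        k = rng.choice(len(iv), p=lens / lens.sum())
        return int(rng.integers(iv[k, 0], iv[k, 1]))

    peaks = []
    n_inside = 0
    for _ in range(config.n_peaks):
        inside = bool(rng.random() < config.target_overlap_fraction)
        mid = sample_point(reg if inside else comp)
        n_inside += inside
        w = int(rng.integers(*config.peak_width_range))
        s = max(0, mid - w // 2)
        e = min(L, s + w)
        # keep the midpoint on the intended side of the region boundary
        peaks.append((mid, mid + 1) if e - s < 1 else (s, e))
    # construction merges overlapping peaks, so the achieved fraction is
    # recomputed from the emitted (merged) intervals' midpoints
    out = IntervalSet({chrom: np.asarray(peaks, dtype=np.int64)})
    mids = (out.intervals[chrom][:, 0] + out.intervals[chrom][:, 1]) // 2
    achieved = float(regions.contains_points(chrom, mids).mean())
    return out, achieved
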
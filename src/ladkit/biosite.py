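"""Biotinylation-site post-processing for proximity-labeling (BioID/BioSITe).

Site-level anti-biotin capture yields one row per biotinylated-peptide
observation: protein, lysine position, condition, replicate, MS1 abundance.
This module aggregates sites to proteins, forms per-replicate bait/control
abundance ratios, flags enrichment at a fold threshold (2.0 for the
bait-vs-tracer comparison, 1.6 for the +shield/−shield LAD-directed
comparison), ranks proteins by degree of biotinylation (biotinylated lysines
over total lysines), and maps site positions onto membrane-topology domains.

Quantification follows ratio-of-sums-then-mean: per replicate the protein's
site abundances are summed, one numerator/denominator ratio is taken per
replicate, and the arithmetic mean of replicate ratios is compared with the
threshold ("average ratio between replicates"). A geometric-mean alternative
is available via ``ratio_mean="geometric"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "BiotinSiteRecord",
    "ProteinSiteSummary",
    "DegreeOfBiotinylation",
    "TopologyAnnotation",
    "load_site_table",
    "summarize_proteins",
    "compute_enrichment",
    "degree_of_biotinylation",
    "map_site_topology",
    "write_summary_tsv",
]

THRESHOLD_BAIT_VS_TRACER = 2.0   # LAP2β bait over m6A-tracer control
THRESHOLD_SHIELD = 1.6           # +shield over −shield (LAD-directed)

REQUIRED_COLUMNS = ("protein_id", "site_pos", "residue", "condition", "replicate", "abundance")

TOPOLOGY_LABELS = {"lumenal", "nucleoplasmic", "cytoplasmic", "transmembrane", "other"}


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class BiotinSiteRecord:
    """One biotinylated-peptide observation (site-resolved)."""

    protein_id: str
    site_pos: int          # 1-based residue index of the modified lysine
    residue: str
    condition: str
    replicate: int
    abundance: float       # MS1 intensity, arbitrary units

    def __post_init__(self) -> None:
        if self.site_pos < 1:
            raise ValueError(f"{self.protein_id}: site_pos must be >= 1")
        if self.abundance < 0:
            raise ValueError(f"{self.protein_id}: negative abundance")


@dataclass
class ProteinSiteSummary:
    protein_id: str
    n_sites: int
    # (condition, replicate) -> summed abundance
    abundance: dict[tuple[str, int], float] = field(default_factory=dict)
    # replicate -> numerator/denominator ratio
    ratios: dict[int, float] = field(default_factory=dict)
    mean_ratio: float | None = None
    enriched: bool | None = None
    imputed: bool = False
    n_replicates: int = 0


@dataclass(frozen=True)
class DegreeOfBiotinylation:
    protein_id: str
    biotinylated_lysines: int
    total_lysines: int
    degree: float
    error: str | None = None


@dataclass(frozen=True)
class TopologyAnnotation:
    """1-based inclusive residue ranges labelled with a compartment."""

    protein_id: str
    domains: tuple[tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        for s, e, lab in self.domains:
            if lab not in TOPOLOGY_LABELS:
                raise ValueError(f"{self.protein_id}: unknown topology label {lab!r}")
            if not (1 <= s <= e):
                raise ValueError(f"{self.protein_id}: invalid domain range {s}-{e}")
        ordered = sorted(self.domains)
        for (s1, e1, _), (s2, _e2, _) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.protein_id}: overlapping domain ranges")


def load_site_table(path: str, strict_residue: bool = False) -> list[BiotinSiteRecord]:
    """Parse a biotinylation-site TSV into typed records.

    Required columns: protein_id, site_pos, residue, condition, replicate,
    abundance. Only biotinylated-lysine rows belong in this table; with
    ``strict_residue`` any non-K residue row raises, otherwise it is kept
    with a warning (some accessions report modified N-termini).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"site table missing required columns: {', '.join(missing)}")
    if df.empty:
        warnings.warn(f"{path}: empty site table")
        return []
    records = []
    for row in df.itertuples(index=False):
        residue = str(row.residue)
        if residue != "K":
            msg = f"{row.protein_id} site {row.site_pos}: residue {residue!r} is not K"
            if strict_residue:
                raise ValueError(msg)
            warnings.warn(msg)
        records.append(
            BiotinSiteRecord(
                protein_id=str(row.protein_id),
                site_pos=int(row.site_pos),
                residue=residue,
                condition=str(row.condition),
                replicate=int(row.replicate),
                abundance=float(row.abundance),
            )
        )
    return records


def summarize_proteins(records: list[BiotinSiteRecord]) -> list[ProteinSiteSummary]:
    """Protein-level aggregation: summed abundance per condition/replicate,
    distinct-site count across all conditions. Sites collapse on
    (protein_id, site_pos)."""
    if not records:
        raise ValueError("no site records to summarize")
    by_protein: dict[str, ProteinSiteSummary] = {}
    sites: dict[str, set[int]] = {}
    for r in records:
        s = by_protein.get(r.protein_id)
        if s is None:
            s = by_protein[r.protein_id] = ProteinSiteSummary(r.protein_id, 0)
            sites[r.protein_id] = set()
        sites[r.protein_id].add(r.site_pos)
        key = (r.condition, r.replicate)
        s.abundance[key] = s.abundance.get(key, 0.0) + r.abundance
    for pid, s in by_protein.items():
        s.n_sites = len(sites[pid])
    return sorted(by_protein.values(), key=lambda s: s.protein_id)


def compute_enrichment(
    summaries: list[ProteinSiteSummary],
    numerator_condition: str,
    denominator_condition: str,
    threshold: float = THRESHOLD_BAIT_VS_TRACER,
    ratio_mean: str = "arithmetic",
) -> list[ProteinSiteSummary]:
    """Per-replicate ratios, their mean, and the enrichment flag.

    For each replicate present in both conditions for a protein, ratio =
    numerator abundance / denominator abundance. A zero denominator in a
    replicate is imputed as the smallest positive abundance observed in that
    replicate of the denominator condition (a detection floor; flagged
    ``imputed``). mean_ratio is the arithmetic (default) or geometric mean
    of the per-replicate ratios; ``enriched`` iff mean_ratio > threshold.
    Proteins absent from the numerator condition entirely are excluded with
    a warning.
    """
    if ratio_mean not in ("arithmetic", "geometric"):
        raise ValueError("ratio_mean must be 'arithmetic' or 'geometric'")

    # detection floor per denominator replicate, over all proteins
    floor: dict[int, float] = {}
    for s in summaries:
        for (cond, rep), a in s.abundance.items():
            if cond == denominator_condition and a > 0:
                floor[rep] = min(floor.get(rep, np.inf), a)

    out: list[ProteinSiteSummary] = []
    for s in summaries:
        num_reps = {r for (c, r) in s.abundance if c == numerator_condition}
        den_reps = {r for (c, r) in s.abundance if c == denominator_condition}
        if not num_reps:
            warnings.warn(f"{s.protein_id}: absent from condition {numerator_condition!r}; excluded")
            continue
        reps = sorted(num_reps & den_reps) or sorted(num_reps)
        ratios: dict[int, float] = {}
        imputed = False
        for rep in reps:
            num = s.abundance.get((numerator_condition, rep), 0.0)
            den = s.abundance.get((denominator_condition, rep), 0.0)
            if den <= 0:
                if rep not in floor:
                    raise ValueError(
                        f"no replicates in common and no detection floor for replicate {rep}"
                    )
                den = floor[rep]
                imputed = True
            ratios[rep] = num / den
        vals = np.asarray(list(ratios.values()))
        mean = float(vals.mean()) if ratio_mean == "arithmetic" else float(
            np.exp(np.log(np.maximum(vals, np.finfo(float).tiny)).mean())
        )
        s.ratios = ratios
        s.mean_ratio = mean
        s.enriched = mean > threshold
        s.imputed = imputed
        s.n_replicates = len(ratios)
        out.append(s)
    return out


def _read_proteome(proteome_fasta: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(proteome_fasta, "fasta")}


def degree_of_biotinylation(
    records: list[BiotinSiteRecord], proteome_fasta: str
) -> list[DegreeOfBiotinylation]:
    """Biotinylated lysines / total lysines per protein, ranked descending.

    total_lysines counts K in the protein sequence; biotinylated_lysines
    counts distinct modified positions. A protein missing from the FASTA, a
    site beyond the sequence, a non-K residue at a claimed site, or a
    lysine-free sequence each yield an error record (degree NaN) while the
    rest proceed. Ties in degree break by protein_id.
    """
    seqs = _read_proteome(proteome_fasta)
    sites: dict[str, set[int]] = {}
    for r in records:
        sites.setdefault(r.protein_id, set()).add(r.site_pos)

    results: list[DegreeOfBiotinylation] = []
    for pid in sorted(sites):
        positions = sites[pid]
        seq = seqs.get(pid)
        if seq is None:
            results.append(DegreeOfBiotinylation(pid, 0, 0, float("nan"),
                                                 error="protein missing from proteome FASTA"))
            continue
        total_k = seq.count("K")
        bad = sorted(p for p in positions if p > len(seq) or seq[p - 1] != "K")
        if bad:
            results.append(DegreeOfBiotinylation(pid, 0, total_k, float("nan"),
                                                 error=f"site integrity error at position(s) {bad}"))
            continue
        if total_k == 0:
            results.append(DegreeOfBiotinylation(pid, 0, 0, float("nan"),
                                                 error="no lysines in sequence"))
            continue
        results.append(DegreeOfBiotinylation(pid, len(positions), total_k,
                                             len(positions) / total_k))
    ok = sorted((r for r in results if r.error is None),
                key=lambda r: (-r.degree, r.protein_id))
    errs = [r for r in results if r.error is not None]
    return ok + errs


def map_site_topology(
    records: list[BiotinSiteRecord],
    annotations: dict[str, TopologyAnnotation],
) -> list[tuple[str, int, str]]:
    """Label each distinct site with the compartment of its residue range.

    Returns (protein_id, site_pos, label) tuples; label is "unannotated"
    when the protein has no annotation and "unassigned" when the site falls
    in no annotated domain. Sites past the annotated extent raise.
    """
    out: list[tuple[str, int, str]] = []
    seen: set[tuple[str, int]] = set()
    for r in records:
        key = (r.protein_id, r.site_pos)
        if key in seen:
            continue
        seen.add(key)
        ann = annotations.get(r.protein_id)
        if ann is None:
            out.append((r.protein_id, r.site_pos, "unannotated"))
            continue
        extent = max(e for _s, e, _l in ann.domains)
        if r.site_pos > extent:
            raise ValueError(
                f"{r.protein_id}: site {r.site_pos} beyond annotated extent {extent}"
            )
        label = "unassigned"
        for s, e, lab in ann.domains:
            if s <= r.site_pos <= e:
                label = lab
                break
        out.append((r.protein_id, r.site_pos, label))
    return out


def load_topology_tsv(path: str) -> dict[str, TopologyAnnotation]:
    """Topology TSV: protein_id, start, end, label (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    for c in ("protein_id", "start", "end", "label"):
        if c not in df.columns:
            raise SchemaError(f"topology table missing column {c!r}")
    out = {}
    for pid, grp in df.groupby("protein_id"):
        domains = tuple(
            (int(r.start), int(r.end), str(r.label)) for r in grp.itertuples(index=False)
        )
        out[str(pid)] = TopologyAnnotation(str(pid), domains)
    return out


def write_summary_tsv(summaries: list[ProteinSiteSummary], path: str,
                      degrees: list[DegreeOfBiotinylation] | None = None) -> None:
    deg = {d.protein_id: d.degree for d in degrees or []}
    rows = []
    for s in summaries:
        row: dict = {
            "protein_id": s.protein_id,
            "n_sites": s.n_sites,
            "mean_ratio": s.mean_ratio,
            "enriched": s.enriched,
            "imputed": s.imputed,
            "n_replicates": s.n_replicates,
        }
        for rep, ratio in sorted(s.ratios.items()):
            row[f"ratio_rep{rep}"] = ratio
        for (cond, rep), a in sorted(s.abundance.items()):
            row[f"abundance_{cond}_rep{rep}"] = a
        if deg:
            row["degree_of_biotinylation"] = deg.get(s.protein_id)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
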
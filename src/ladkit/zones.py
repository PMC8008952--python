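"""Integration of nuclear-periphery protein sets: meta-laminome, Venn
accounting, and zone assignment at the INM/lamina/LAD interface.

Zones partition the protein universe by where a protein acts:

* zone 1 — restricted to the INM/lamina (in the laminome or bait interactome
  but never LAD-proximal);
* zone 2 — the "middlemen" at the lamina–chromatin interface (LAD-proximal
  AND in the laminome/bait interactome);
* zone 3 — restricted to LADs (LAD-proximal only);
* none  — in the declared universe but in no input set.

The meta-laminome applies the published-study consensus rule: a protein
counts when observed in at least ``min_studies`` (default 3) of the four
published lamina interactome datasets.

Gene symbols are normalised (uppercase, trimmed, optional synonym table)
before any set algebra, since the source lists mix species casing and
aliases (Lap2β/TMPO, HP1α/CBX5).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

__all__ = [
    "ZoneAssignment",
    "normalize_symbols",
    "load_synonym_table",
    "meta_laminome",
    "assign_zones",
    "venn_counts",
    "micro_fixture",
]


class SynonymTableError(ValueError):
    pass


@dataclass(frozen=True)
class ZoneAssignment:
    """Partition of the universe: symbol -> zone in {1, 2, 3, 'none'}."""

    zones: dict[str, object]

    def members(self, zone) -> set[str]:
        return {p for p, z in self.zones.items() if z == zone}

    def counts(self) -> dict:
        out: dict = {1: 0, 2: 0, 3: 0, "none": 0}
        for z in self.zones.values():
            out[z] += 1
        return out


def load_synonym_table(path: str) -> dict[str, str]:
    """TSV with columns alias, canonical; aliases matched case-insensitively."""
    df = pd.read_csv(path, sep="\t")
    for c in ("alias", "canonical"):
        if c not in df.columns:
            raise SynonymTableError(f"synonym table missing column {c!r}")
    table: dict[str, str] = {}
    for r in df.itertuples(index=False):
        alias = str(r.alias).strip().upper()
        canonical = str(r.canonical).strip().upper()
        if alias in table and table[alias] != canonical:
            raise SynonymTableError(
                f"alias {alias!r} maps to both {table[alias]!r} and {canonical!r}"
            )
        table[alias] = canonical
    return table


def normalize_symbols(raw, synonyms: dict[str, str] | None = None) -> set[str]:
    """Uppercase, strip, and resolve aliases through the synonym table."""
    out = set()
    for s in raw:
        sym = str(s).strip().upper()
        if not sym:
            continue
        if synonyms:
            sym = synonyms.get(sym, sym)
        out.add(sym)
    return out


def meta_laminome(memberships: dict[str, set[str]], min_studies: int = 3) -> set[str]:
    """Consensus lamina proteome: present in >= min_studies of the datasets."""
    if min_studies > len(memberships):
        raise ValueError(
            f"min_studies={min_studies} exceeds the {len(memberships)} declared datasets"
        )
    tally: dict[str, int] = {}
    for proteins in memberships.values():
        for p in proteins:
            tally[p] = tally.get(p, 0) + 1
    return {p for p, n in tally.items() if n >= min_studies}


def assign_zones(
    laminome: set[str],
    lap2b: set[str],
    ladome: set[str],
    universe: set[str] | None = None,
) -> ZoneAssignment:
    """Zone partition from the three membership sets.

    zone 1 = (laminome ∪ lap2b) \\ ladome; zone 2 = ladome ∩ (laminome ∪
    lap2b); zone 3 = ladome \\ (laminome ∪ lap2b); none = universe minus all
    three. Default universe is the union of the inputs.
    """
    inm = laminome | lap2b
    if universe is None:
        universe = inm | ladome
    zones: dict[str, object] = {}
    for p in universe:
        if p in ladome and p in inm:
            zones[p] = 2
        elif p in inm:
            zones[p] = 1
        elif p in ladome:
            zones[p] = 3
        else:
            zones[p] = "none"
    assignment = ZoneAssignment(zones)
    c = assignment.counts()
    assert sum(c.values()) == len(universe)
    return assignment


def venn_counts(named_sets: dict[str, set[str]]) -> dict[frozenset, int]:
    """Counts over every non-empty disjoint region of up to 4 sets.

    Keys are frozensets of the set names defining the region (exactly those
    sets the region's elements belong to); regions sum to |union|.
    """
    if len(named_sets) > 4:
        raise ValueError("venn_counts supports at most 4 sets; use a membership table instead")
    names = list(named_sets)
    out: dict[frozenset, int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(named_sets[n] for n in combo))
            outside = set.union(set(), *(named_sets[n] for n in names if n not in combo))
            out[frozenset(combo)] = len(inside - outside)
    return out


def load_symbol_list(path: str) -> list[str]:
    """One symbol per row; a single-column TSV with or without a header."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            sym = line.strip().split("\t")[0]
            if not sym or (i == 0 and sym.lower() in {"symbol", "protein", "gene", "protein_id"}):
                continue
            out.append(sym)
    return out


def micro_fixture() -> dict[str, set[str]]:
    """A 12-protein worked example of the three input sets.

    Composed of well-known nuclear-periphery proteins so each zone is
    populated: lamins and LEM-domain proteins at the INM/lamina, the
    LAP2β interactome, and LAD-proximal chromatin factors.
    """
    laminome = {"LMNA", "LMNB1", "LMNB2", "EMD", "TMPO", "LBR", "SUN1"}
    lap2b = {"TMPO", "EMD", "LMNB1", "LMNA", "SUN2"}
    ladome = {"LMNB1", "EMD", "PRR14", "RIF1", "MECP2", "SMCHD1"}
    return {"laminome": laminome, "lap2b": lap2b, "ladome": ladome}
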
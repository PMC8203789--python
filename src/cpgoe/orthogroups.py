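"""Orthogroup-level methylation concordance across species.

Consumes an orthogroup membership table (Orthogroups.tsv dialect: header of
species names, first column the OG id, cells holding comma+space separated
gene lists, empty cell meaning the species has no member) together with
per-species low/high methylation calls, and produces per-OG per-species
status, UpSet-style exclusive intersection counts, and species-specific
gene fractions per category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

LOW, HIGH, MIXED, ABSENT = "low", "high", "mixed", "absent"


@dataclass
class OrthogroupTable:
    """OG -> species -> member genes, plus per-species unassigned genes."""

    og_members: dict[str, dict[str, list[str]]]
    unassigned: dict[str, list[str]] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for members in self.og_members.values():
            for sp in members:
                seen.setdefault(sp)
        for sp in self.unassigned:
            seen.setdefault(sp)
        return list(seen)

    def og_of_gene(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for og, members in self.og_members.items():
            for genes in members.values():
                for g in genes:
                    out[g] = og
        return out


def read_orthogroups_tsv(
    path: str | Path, unassigned_path: str | Path | None = None
) -> OrthogroupTable:
    """Parse an Orthogroups.tsv membership table.

    Rejects duplicate OG ids and genes listed in more than one OG.  An
    optional second table of the same dialect carries unassigned
    (species-specific, no-OG) genes.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    og_col = df.columns[0]
    species = list(df.columns[1:])
    if df[og_col].duplicated().any():
        dup = df[og_col][df[og_col].duplicated()].iloc[0]
        raise ValueError(f"duplicate OG id '{dup}'")
    seen_genes: dict[str, str] = {}
    og_members: dict[str, dict[str, list[str]]] = {}
    for _, row in df.iterrows():
        og = row[og_col]
        members: dict[str, list[str]] = {}
        for sp in species:
            cell = row[sp].strip()
            genes = [g.strip() for g in cell.split(",") if g.strip()] if cell else []
            for g in genes:
                if g in seen_genes and seen_genes[g] != og:
                    raise ValueError(
                        f"gene '{g}' listed in both '{seen_genes[g]}' and '{og}'"
                    )
                seen_genes[g] = og
            if genes:
                members[sp] = genes
        og_members[og] = members
    table = OrthogroupTable(og_members=og_members)
    if unassigned_path is not None:
        un = pd.read_csv(unassigned_path, sep="\t", dtype=str, keep_default_na=False)
        for sp in un.columns:
            genes: list[str] = []
            for cell in un[sp]:
                genes.extend(g.strip() for g in cell.split(",") if g.strip())
            if genes:
                table.unassigned[sp] = genes
    return table


def assign_og_status(
    table: OrthogroupTable,
    calls: Mapping[str, Mapping[str, str]],
    rule: str = "strict",
) -> dict[str, dict[str, str]]:
    """Per-OG per-species methylation status.

    ``calls`` maps species -> (gene -> "low"/"high").  Under the default
    strict rule an OG is low (high) in a species only when every called
    member gene is low (high); anything else is mixed.  Members without a
    call (genes dropped by the CpG_o/e filter) are ignored; a species whose
    members all lack calls, or with no members, is absent.  ``rule`` may be
    "majority" for a sensitivity variant (ties -> mixed).
    """
    if rule not in ("strict", "majority"):
        raise ValueError(f"unknown OG status rule '{rule}'")
    status: dict[str, dict[str, str]] = {}
    all_species = table.species
    for og, members in table.og_members.items():
        row: dict[str, str] = {}
        for sp in all_species:
            genes = members.get(sp, [])
            cats = [calls[sp][g] for g in genes if g in calls.get(sp, {})]
            if not cats:
                row[sp] = ABSENT
            elif rule == "strict":
                if all(c == LOW for c in cats):
                    row[sp] = LOW
                elif all(c == HIGH for c in cats):
                    row[sp] = HIGH
                else:
                    row[sp] = MIXED
            else:
                n_low = sum(1 for c in cats if c == LOW)
                n_high = len(cats) - n_low
                row[sp] = LOW if n_low > n_high else HIGH if n_high > n_low else MIXED
        status[og] = row
    return status


def upset_exclusive_counts(
    status: Mapping[str, Mapping[str, str]],
    categories: Iterable[str] = (LOW, HIGH),
) -> dict[frozenset[tuple[str, str]], int]:
    """Exclusive intersection counts over the (species, category) sets.

    Each (species, category) label defines the set of OGs whose status in
    that species is exactly that category; mixed and absent statuses place
    the OG in no set for that species.  Every OG belonging to at least one
    set is counted under the exact combination of sets that contain it, so
    the counts partition the union — the quantities an UpSet plot displays.
    """
    categories = set(categories)
    counts: dict[frozenset[tuple[str, str]], int] = {}
    for og, row in status.items():
        pattern = frozenset(
            (sp, cat) for sp, cat in row.items() if cat in categories
        )
        if pattern:
            counts[pattern] = counts.get(pattern, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: -kv[1]))


def upset_counts_frame(
    counts: Mapping[frozenset[tuple[str, str]], int]
) -> pd.DataFrame:
    rows = [
        {"pattern": "&".join(sorted(f"{sp}:{cat}" for sp, cat in pat)), "count": n}
        for pat, n in counts.items()
    ]
    return pd.DataFrame(rows).sort_values(
        ["count", "pattern"], ascending=[False, True], ignore_index=True
    )


def species_specific_fraction(
    table: OrthogroupTable,
    calls: Mapping[str, Mapping[str, str]],
    species: str,
) -> dict[str, float]:
    """Fraction of species-specific genes within each methylation bin.

    A gene is species-specific when it is unassigned to any OG, or its OG
    contains genes from no other species.  Fractions are computed within the
    called low and high bins of the given species.
    """
    sp_calls = calls.get(species, {})
    gene_og = table.og_of_gene()
    multi_species_ogs = {
        og for og, members in table.og_members.items() if len(members) > 1
    }
    frac: dict[str, float] = {}
    for cat in (LOW, HIGH):
        genes = [g for g, c in sp_calls.items() if c == cat]
        if not genes:
            frac[cat] = float("nan")
            continue
        n_specific = sum(
            1 for g in genes if gene_og.get(g) not in multi_species_ogs
        )
        frac[cat] = n_specific / len(genes)
    return frac
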
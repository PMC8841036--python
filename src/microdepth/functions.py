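"""Rule-based functional-group mapping (a miniature of the FAPROTAX idea).

Rules are (rank:name, group) pairs in a two-column TSV: an ASV contributes
its reads to every group whose pattern matches its lineage at the stated
rank, with exact case-insensitive matching. A taxon may feed several
groups and a group may have several patterns; nothing is normalized across
groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountTable, TaxonomyTable, ValidationError, RANKS

DEFAULT_RULES = Path(__file__).parent / "data" / "function_rules.tsv"


@dataclass
class FunctionRule:
    rank: str
    name: str   # taxon name at that rank, matched case-insensitively
    group: str


@dataclass
class FunctionRules:
    rules: list[FunctionRule]

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValidationError("empty function rules")
        for r in self.rules:
            if r.rank not in RANKS:
                raise ValidationError(f"rule rank {r.rank!r} not in {RANKS}")
            if not r.name or not r.group:
                raise ValidationError("rule patterns and groups must be non-empty")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FunctionRules":
        rules = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValidationError(f"{path}:{ln}: expected 2 tab-separated fields")
                pattern, group = parts
                if ":" not in pattern:
                    raise ValidationError(f"{path}:{ln}: pattern must be 'rank:Name'")
                rank, name = pattern.split(":", 1)
                rules.append(FunctionRule(rank.strip().lower(), name.strip(), group.strip()))
        return cls(rules)

    @property
    def groups(self) -> list[str]:
        seen = []
        for r in self.rules:
            if r.group not in seen:
                seen.append(r.group)
        return seen


def map_functions(table: CountTable, taxonomy: TaxonomyTable,
                  rules: FunctionRules):
    """Assign ASVs to functional groups and sum their reads per sample.

    Returns (sample x group DataFrame, asv -> [groups] dict,
    assigned-ASV fraction).
    """
    assignments: dict[str, list[str]] = {}
    for asv in table.asv_ids:
        ranks = taxonomy.ranks_of(asv)
        hit = []
        for rule in rules.rules:
            if ranks[rule.rank].lower() == rule.name.lower() and rule.group not in hit:
                hit.append(rule.group)
        if hit:
            assignments[asv] = hit
    groups = rules.groups
    profile = np.zeros((table.n_samples, len(groups)))
    gidx = {g: k for k, g in enumerate(groups)}
    for j, asv in enumerate(table.asv_ids):
        for g in assignments.get(asv, ()):
            profile[:, gidx[g]] += table.counts[:, j]
    group_table = pd.DataFrame(profile, index=pd.Index(table.sample_ids, name="sample_id"),
                               columns=groups)
    assigned_fraction = len(assignments) / table.n_asvs
    return group_table, assignments, assigned_fraction


def function_attribution(table: CountTable, assignments: dict[str, list[str]],
                         taxonomy: TaxonomyTable, rank: str = "phylum") -> pd.DataFrame:
    """Percent of each group's reads contributed by each taxon at ``rank``.

    Percentages within a group sum to 100; groups with zero reads are
    flagged with NaN percentages.
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}")
    totals = dict(zip(table.asv_ids, table.counts.sum(axis=0)))
    contrib: dict[str, dict[str, float]] = {}
    for asv, groups in assignments.items():
        taxon = taxonomy.name_at(asv, rank)
        for g in groups:
            contrib.setdefault(g, {})
            contrib[g][taxon] = contrib[g].get(taxon, 0.0) + float(totals[asv])
    rows = []
    for g, taxa in contrib.items():
        total = sum(taxa.values())
        for taxon, reads in sorted(taxa.items(), key=lambda kv: -kv[1]):
            pct = 100.0 * reads / total if total > 0 else float("nan")
            rows.append({"group": g, rank: taxon, "reads": reads, "percent": pct})
    return pd.DataFrame(rows)
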
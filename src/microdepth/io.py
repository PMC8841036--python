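"""Domain types and tabular I/O for sample x ASV community data.

All tables are plain TSV with a header row; the first column holds the
identifiers (sample or ASV ids). Count tables are oriented samples-as-rows,
ASVs-as-columns, matching community-ecology convention.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("microdepth")

RANKS = ("domain", "phylum", "class", "order", "family", "genus")
LAYERS = ("S", "M", "D")
NUTRIENT_VARS = ("TC", "TN", "DOC", "DON", "NH4", "NO3")
SOIL_VARS = NUTRIENT_VARS + ("moisture", "pH", "clay", "silt", "sand")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class CountTable:
    """Sample x ASV matrix of non-negative integer read counts."""

    sample_ids: list[str]
    asv_ids: list[str]
    counts: np.ndarray  # shape (n_samples, n_asvs), integer

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.asv_ids = [str(a) for a in self.asv_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.asv_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.asv_ids)} ASVs"
            )
        if counts.size == 0:
            raise ValidationError("count table must have at least 1 sample and 1 ASV")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            bad = np.argwhere(~np.isclose(counts, rounded, atol=0, rtol=0))
            if bad.size:
                i, j = bad[0]
                raise ValidationError(
                    f"non-integer count {counts[i, j]!r} at sample "
                    f"{self.sample_ids[i]!r}, ASV {self.asv_ids[j]!r}"
                )
            counts = rounded.astype(np.int64)
        if (counts < 0).any():
            i, j = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, ASV {self.asv_ids[j]!r}"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.asv_ids, "ASV")
        self.counts = counts.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.asv_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        keep = [s for s in sample_ids]
        idx = [self.sample_ids.index(s) for s in keep]
        return CountTable(keep, list(self.asv_ids), self.counts[idx])

    def subset_asvs(self, asv_ids: Iterable[str]) -> "CountTable":
        keep = [a for a in asv_ids]
        idx = [self.asv_ids.index(a) for a in keep]
        return CountTable(list(self.sample_ids), keep, self.counts[:, idx])


@dataclass
class SampleMetadata:
    """Per-sample design factors: plot, soil layer (S/M/D) and sampling time."""

    table: pd.DataFrame  # index sample_id, columns plot, layer, time

    def __post_init__(self) -> None:
        df = self.table
        required = {"plot", "layer", "time"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate sample identifier in metadata: {dup!r}")
        bad = set(df["layer"].astype(str)) - set(LAYERS)
        if bad:
            raise ValidationError(
                f"layer values {sorted(bad)} outside the declared set {LAYERS}"
            )
        self.table = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index.astype(str))

    def layer_of(self) -> pd.Series:
        return self.table["layer"].astype(str)

    def samples_in_layer(self, layer: str) -> list[str]:
        return list(self.table.index[self.table["layer"].astype(str) == layer])

    def validate_against(self, table: CountTable) -> None:
        missing = [s for s in table.sample_ids if s not in set(self.sample_ids)]
        if missing:
            raise ValidationError(
                f"samples missing from metadata: {missing[:5]}"
            )


@dataclass
class TaxonomyTable:
    """ASV -> semicolon-delimited lineage (domain;phylum;...;genus).

    ASVs absent from the table, and empty ranks, are treated as unclassified.
    """

    lineages: dict[str, str]

    def ranks_of(self, asv_id: str) -> dict[str, str]:
        lineage = self.lineages.get(asv_id, "")
        parts = [p.strip() for p in lineage.split(";")] if lineage else []
        out = {}
        for i, rank in enumerate(RANKS):
            name = parts[i] if i < len(parts) else ""
            out[rank] = name if name else "unclassified"
        return out

    def name_at(self, asv_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return self.ranks_of(asv_id)[rank]

    def unclassified_proportions(self, asv_ids: Sequence[str]) -> pd.Series:
        """Per-rank fraction of ASVs lacking a name at that rank."""
        counts = {r: 0 for r in RANKS}
        for a in asv_ids:
            ranks = self.ranks_of(a)
            for r in RANKS:
                if ranks[r] == "unclassified":
                    counts[r] += 1
        n = max(len(asv_ids), 1)
        return pd.Series({r: counts[r] / n for r in RANKS}, name="unclassified_proportion")


@dataclass
class SoilVariables:
    """Per-sample soil physicochemistry (nutrients, moisture, pH, texture)."""

    table: pd.DataFrame  # index sample_id
    texture_tolerance: float = 1.0

    def __post_init__(self) -> None:
        df = self.table
        conc = [v for v in NUTRIENT_VARS if v in df.columns]
        for v in conc:
            if (df[v] < 0).any():
                s = df.index[df[v] < 0][0]
                raise ValidationError(f"negative {v} concentration for sample {s!r}")
        tex = ["clay", "silt", "sand"]
        if all(t in df.columns for t in tex):
            total = df[tex].sum(axis=1)
            off = (total - 100.0).abs() > self.texture_tolerance
            if off.any():
                s = df.index[off][0]
                raise ValidationError(
                    f"clay+silt+sand = {total[s]:.3f} for sample {s!r}, "
                    f"outside 100 +/- {self.texture_tolerance}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index.astype(str))


@dataclass
class AnalysisConfig:
    """All fixed constants of the downstream analysis.

    Thresholds are fractions of total reads: rare < 1e-4 (0.01%), abundant
    > 1e-3 (0.1%); the network keeps ASVs above 5e-3 (0.5%) present in more
    than half the communities, with |rho| >= 0.8 and BH q <= 0.001 edges.
    """

    rarefaction_depth: int | None = None
    rare_threshold: float = 1e-4
    abundant_threshold: float = 1e-3
    network_abundance_threshold: float = 5e-3
    network_occurrence_threshold: float = 0.5
    rho_min: float = 0.8
    q_max: float = 0.001
    n_permutations: int = 999
    zi_threshold: float = 2.5
    pi_threshold: float = 0.62
    enrichment_q: float = 0.05
    rf_trees: int = 500
    rf_response_permutations: int = 99
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.rare_threshold < self.abundant_threshold < 1):
            raise ValidationError(
                "thresholds must satisfy 0 < rare_threshold < abundant_threshold < 1"
            )
        if not (0 < self.rho_min <= 1):
            raise ValidationError("rho_min must be in (0, 1]")
        for name in ("network_abundance_threshold", "network_occurrence_threshold",
                     "q_max", "zi_threshold", "pi_threshold", "enrichment_q"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        for name in ("n_permutations", "rf_trees", "rf_response_permutations"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        if self.rarefaction_depth is not None and self.rarefaction_depth < 1:
            raise ValidationError("rarefaction_depth must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# Readers / writers


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    return df


def read_counts(path: str | Path) -> CountTable:
    df = _read_tsv(path)
    arr = df.to_numpy()
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        raise ValidationError(f"non-numeric count cell in {path}")
    if not np.issubdtype(arr.dtype, np.integer):
        bad = np.argwhere(arr != np.rint(arr))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"non-integer count {arr[i, j]!r} at sample {df.index[i]!r}, "
                f"ASV {df.columns[j]!r}"
            )
    return CountTable.from_dataframe(df)


def read_metadata(path: str | Path) -> SampleMetadata:
    return SampleMetadata(_read_tsv(path))


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    df = _read_tsv(path)
    if "lineage" not in df.columns:
        raise ValidationError(f"taxonomy table {path} must have a 'lineage' column")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate ASV identifier in taxonomy: {dup!r}")
    return TaxonomyTable(df["lineage"].fillna("").astype(str).to_dict())


def read_soil(path: str | Path) -> SoilVariables:
    return SoilVariables(_read_tsv(path))


def write_counts(table: CountTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, sep="\t")


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id")


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    pd.Series(tax.lineages, name="lineage").to_csv(
        path, sep="\t", index_label="asv_id")


def write_soil(soil: SoilVariables, path: str | Path) -> None:
    soil.table.to_csv(path, sep="\t", index_label="sample_id")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def load_dataset(
    count_path: str | Path,
    metadata_path: str | Path,
    taxonomy_path: str | Path | None = None,
    soil_path: str | Path | None = None,
) -> tuple[CountTable, SampleMetadata, TaxonomyTable | None, SoilVariables | None]:
    """Load and cross-validate the full input bundle.

    Every count-table sample must appear in the metadata; ASVs without a
    taxonomy row are logged and treated as unclassified.
    """
    counts = read_counts(count_path)
    meta = read_metadata(metadata_path)
    meta.validate_against(counts)
    taxonomy = read_taxonomy(taxonomy_path) if taxonomy_path else None
    if taxonomy is not None:
        missing = [a for a in counts.asv_ids if a not in taxonomy.lineages]
        if missing:
            logger.warning(
                "%d ASVs missing from taxonomy (treated as unclassified), e.g. %s",
                len(missing), missing[:3])
    soil = read_soil(soil_path) if soil_path else None
    if soil is not None:
        missing = [s for s in counts.sample_ids if s not in set(soil.sample_ids)]
        if missing:
            logger.warning("%d samples missing soil variables, e.g. %s",
                           len(missing), missing[:3])
    return counts, meta, taxonomy, soil


# ---------------------------------------------------------------------------
# Relative abundance


def relative_abundance(table: CountTable, basis: str = "per_sample"):
    """Fractional abundances.

    per_sample: DataFrame where each row sums to 1.
    dataset_total: Series of ASV total reads / grand total, summing to 1.
    """
    if basis == "per_sample":
        totals = table.sample_totals()
        zero = np.flatnonzero(totals == 0)
        if zero.size:
            raise ValidationError(
                f"all-zero sample under per_sample basis: {table.sample_ids[zero[0]]!r}")
        frac = table.counts / totals[:, None]
        return pd.DataFrame(frac, index=table.sample_ids, columns=table.asv_ids)
    if basis == "dataset_total":
        grand = table.counts.sum()
        if grand == 0:
            raise ValidationError("count table has no reads")
        return pd.Series(table.counts.sum(axis=0) / grand, index=table.asv_ids)
    raise ValueError(f"unknown basis {basis!r}; use 'per_sample' or 'dataset_total'")
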
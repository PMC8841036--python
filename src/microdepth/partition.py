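"""Rarefaction, rare/abundant partitioning, and layer-enrichment analysis.

The rare biosphere is defined on dataset-total relative abundance: an ASV
below 0.01% of all reads is "rare", above 0.1% "abundant", anything in
between "intermediate". Layer enrichment is a per-ASV Kruskal-Wallis test
of per-sample relative abundance across the three soil layers with BH-FDR
control; a significant ASV is assigned to the layer where its mean
relative abundance peaks (S/M/D), otherwise it is unenriched (U).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import (CountTable, SampleMetadata, ValidationError, LAYERS,
                 relative_abundance)
from .network import fdr_bh

logger = logging.getLogger("microdepth")


@dataclass
class AbundanceClass:
    asv_id: str
    dataset_fraction: float
    abundance_class: str  # rare | intermediate | abundant


@dataclass
class EnrichmentResult:
    asv_id: str
    enriched_in: str  # S | M | D | U
    statistic: float
    q_value: float


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Exact multivariate-hypergeometric draw per sample; samples with fewer
    than ``depth`` total reads are dropped with a warning.
    """
    if depth < 1:
        raise ValidationError("rarefaction depth must be >= 1")
    totals = table.sample_totals()
    keep = np.flatnonzero(totals >= depth)
    dropped = [table.sample_ids[i] for i in np.flatnonzero(totals < depth)]
    if dropped:
        logger.warning("rarefy: dropping %d samples below depth %d: %s",
                       len(dropped), depth, dropped)
    if keep.size == 0:
        raise ValidationError(f"all samples have fewer than {depth} reads")
    rng = np.random.default_rng(seed)
    rows = []
    for i in keep:
        row = table.counts[i]
        if totals[i] == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth, method="marginals"))
    return CountTable([table.sample_ids[i] for i in keep], list(table.asv_ids),
                      np.vstack(rows))


def classify_abundance(table: CountTable, rare_threshold: float = 1e-4,
                       abundant_threshold: float = 1e-3) -> list[AbundanceClass]:
    """Exhaustive, exclusive rare/intermediate/abundant partition."""
    if not (0 < rare_threshold < abundant_threshold < 1):
        raise ValidationError("0 < rare_threshold < abundant_threshold < 1 required")
    frac = relative_abundance(table, basis="dataset_total")
    out = []
    for asv, f in frac.items():
        if f < rare_threshold:
            cls = "rare"
        elif f > abundant_threshold:
            cls = "abundant"
        else:
            cls = "intermediate"
        out.append(AbundanceClass(asv, float(f), cls))
    return out


def classes_to_frame(classes: list[AbundanceClass]) -> pd.DataFrame:
    return pd.DataFrame(
        {"asv_id": [c.asv_id for c in classes],
         "dataset_fraction": [c.dataset_fraction for c in classes],
         "abundance_class": [c.abundance_class for c in classes]}
    ).set_index("asv_id")


def rare_proportions(table: CountTable, classes: list[AbundanceClass],
                     metadata: SampleMetadata) -> pd.DataFrame:
    """Per-sample proportion of rare richness and rare reads.

    rare-richness proportion = (# rare ASVs present) / (# ASVs present);
    rare-read proportion = reads in rare ASVs / sample total.
    """
    cls = classes_to_frame(classes)
    if list(cls.index) != list(table.asv_ids):
        cls = cls.reindex(table.asv_ids)
        if cls["abundance_class"].isna().any():
            raise ValidationError("classes do not cover the table's ASVs")
    rare_mask = (cls["abundance_class"] == "rare").to_numpy()
    totals = table.sample_totals()
    if (totals == 0).any():
        s = table.sample_ids[int(np.flatnonzero(totals == 0)[0])]
        raise ValidationError(f"sample with zero total reads: {s!r}")
    present = table.counts > 0
    rich = present.sum(axis=1)
    rare_rich = present[:, rare_mask].sum(axis=1)
    rare_reads = table.counts[:, rare_mask].sum(axis=1)
    out = pd.DataFrame(
        {"rare_richness_proportion": rare_rich / rich,
         "rare_read_proportion": rare_reads / totals},
        index=pd.Index(table.sample_ids, name="sample_id"))
    md = metadata.table.reindex(out.index)
    out["layer"] = md["layer"].astype(str)
    out["time"] = md["time"].astype(str)
    return out


def _layer_groups(table: CountTable, metadata: SampleMetadata):
    layer = metadata.table.reindex(table.sample_ids)["layer"].astype(str)
    groups = {l: np.flatnonzero((layer == l).to_numpy()) for l in LAYERS}
    for l, idx in groups.items():
        if idx.size < 2:
            raise ValidationError(f"layer {l!r} has fewer than 2 samples")
    return groups


def enrichment_classify(table: CountTable, metadata: SampleMetadata,
                        q_cutoff: float = 0.05,
                        time: str | None = None) -> list[EnrichmentResult]:
    """Classify each ASV as enriched in S, M or D, or unenriched (U).

    Kruskal-Wallis on per-sample relative abundance across layers, BH-FDR
    across ASVs; significant ASVs are assigned the layer with the highest
    mean relative abundance. ``time`` optionally restricts to one sampling
    occasion before testing.
    """
    if time is not None:
        keep = [s for s in table.sample_ids
                if str(metadata.table.loc[s, "time"]) == str(time)]
        if not keep:
            raise ValidationError(f"no samples at time {time!r}")
        table = table.subset_samples(keep)
    groups = _layer_groups(table, metadata)
    rel = relative_abundance(table, basis="per_sample").to_numpy()

    stats_arr = np.zeros(table.n_asvs)
    pvals = np.ones(table.n_asvs)
    for j in range(table.n_asvs):
        samples = [rel[groups[l], j] for l in LAYERS]
        flat = np.concatenate(samples)
        if np.allclose(flat, flat[0]):
            continue  # no signal; stat 0, p 1
        h, p = stats.kruskal(*samples)
        stats_arr[j], pvals[j] = h, p
    qvals = fdr_bh(pvals)

    layer_means = np.vstack([rel[groups[l]].mean(axis=0) for l in LAYERS])
    best = np.array(LAYERS)[layer_means.argmax(axis=0)]
    out = []
    for j, asv in enumerate(table.asv_ids):
        cls = str(best[j]) if qvals[j] < q_cutoff else "U"
        out.append(EnrichmentResult(asv, cls, float(stats_arr[j]), float(qvals[j])))
    return out


def ternary_coordinates(table: CountTable, metadata: SampleMetadata) -> pd.DataFrame:
    """Per-ASV mean relative abundance per layer, normalized to sum to 1.

    These are the coordinates of the ternary (S/M/D) plot; ASVs absent from
    every sample get NaN coordinates.
    """
    groups = _layer_groups(table, metadata)
    rel = relative_abundance(table, basis="per_sample").to_numpy()
    means = np.vstack([rel[groups[l]].mean(axis=0) for l in LAYERS]).T
    total = means.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        coords = np.where(total > 0, means / np.where(total > 0, total, 1.0), np.nan)
    return pd.DataFrame(coords, index=pd.Index(table.asv_ids, name="asv_id"),
                        columns=[f"mean_rel_{l}" for l in LAYERS])
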
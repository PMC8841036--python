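"""Synthetic depth- and time-structured soil community generator.

Emulates a balanced plots x times x layers 16S survey: a heavy-tailed
log-normal species-abundance distribution (many rare, few abundant ASVs),
multiplicative layer and time shifts on the latent scale, planted
correlated ASV blocks (network modules) driven by shared per-sample latent
factors, a small plot random intercept, and soil physicochemistry with
depth gradients. Counts are drawn multinomially at a fixed library size,
so compositional closure holds exactly and fold-change is the single
effect-size unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (CountTable, SampleMetadata, SoilVariables, TaxonomyTable,
                 ValidationError, LAYERS, SOIL_VARS)

# Toy lineage pool. Includes the dominant soil phyla plus designated rare
# phyla so phylum summaries and function mapping are exercised end-to-end.
_DOMINANT_LINEAGES = [
    "Bacteria;Actinobacteriota;Actinobacteria;Solirubrobacterales;Solirubrobacteraceae;Solirubrobacter",
    "Bacteria;Actinobacteriota;Actinobacteria;Propionibacteriales;Nocardioidaceae;Nocardioides",
    "Bacteria;Actinobacteriota;Thermoleophilia;Gaiellales;Gaiellaceae;Gaiella",
    "Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales;Xanthobacteraceae;Bradyrhizobium",
    "Bacteria;Proteobacteria;Gammaproteobacteria;Burkholderiales;Comamonadaceae;Ramlibacter",
    "Bacteria;Firmicutes;Bacilli;Bacillales;Bacillaceae;Bacillus",
    "Bacteria;Chloroflexi;Anaerolineae;Anaerolineales;Anaerolineaceae;Anaerolinea",
    "Bacteria;Acidobacteriota;Blastocatellia;Pyrinomonadales;Pyrinomonadaceae;RB41",
    "Bacteria;Gemmatimonadota;Gemmatimonadetes;Gemmatimonadales;Gemmatimonadaceae;Gemmatimonas",
    "Bacteria;Planctomycetota;Planctomycetes;Pirellulales;Pirellulaceae;Pirellula",
    "Bacteria;Myxococcota;Polyangia;Polyangiales;Polyangiaceae;Polyangium",
    "Bacteria;Methylomirabilota;Methylomirabilia;Rokubacteriales;Rokubacteriaceae;Rokubacterium",
    "Archaea;Crenarchaeota;Nitrososphaeria;Nitrososphaerales;Nitrososphaeraceae;Nitrososphaera",
]
_RARE_LINEAGES = [
    "Bacteria;Desulfobacterota;Desulfovibrionia;Desulfovibrionales;Desulfovibrionaceae;Desulfovibrio",
    "Bacteria;Desulfobacterota;Desulfuromonadia;Geobacterales;Geobacteraceae;Geobacter",
    "Bacteria;Cyanobacteria;Cyanobacteriia;Nostocales;Nostocaceae;Nostoc",
    "Bacteria;Halanaerobiaeota;Halanaerobiia;Halanaerobiales;Halanaerobiaceae;Halocella",
    "Archaea;Euryarchaeota;Methanobacteria;Methanobacteriales;Methanobacteriaceae;Methanobacterium",
    "Archaea;Halobacterota;Methanosarcinia;Methanosarciniales;Methanosarcinaceae;Methanosarcina",
    "Bacteria;Latescibacterota;Latescibacteria;Latescibacterales;Latescibacteraceae;Latescibacter",
    "Bacteria;Zixibacteria;Zixibacteria;Zixibacterales;;",
    "Bacteria;Dadabacteria;Dadabacteriia;Dadabacteriales;;",
    "Bacteria;Calditrichota;Calditrichia;Calditrichales;Calditrichaceae;Caldithrix",
]
_UNCLASSIFIED_LINEAGES = ["Bacteria;;;;;", "Bacteria;Chloroflexi;;;;", "Archaea;;;;;"]

# Per-layer soil means (surface, middle, deep): nutrients decline with
# depth, moisture and clay increase, pH rises slightly. Units follow common
# agricultural-soil reporting (g/kg for TC/TN, mg/kg for DOC/DON/NH4/NO3).
_SOIL_LAYER_MEANS = {
    "TC":       (12.0, 8.0, 5.0),
    "TN":       (1.4, 0.9, 0.6),
    "DOC":      (220.0, 150.0, 100.0),
    "DON":      (28.0, 20.0, 14.0),
    "NH4":      (8.0, 6.0, 4.5),
    "NO3":      (14.0, 9.0, 6.0),
    "moisture": (18.0, 21.0, 24.0),
    "pH":       (7.6, 7.9, 8.1),
    "clay":     (22.0, 26.0, 30.0),
    "silt":     (48.0, 47.0, 46.0),
    "sand":     (30.0, 27.0, 24.0),
}


@dataclass
class SimulationParams:
    """Full parameterization of the synthetic dataset.

    Defaults mirror the emulated survey: 6 plots x 4 sampling times x 3
    soil layers = 72 samples; a log-normal(0, sad_sigma) abundance
    distribution; a 4-fold depth shift on 10% of ASVs; no temporal effect;
    three planted 10-ASV correlation modules at high abundance.
    """

    n_plots: int = 6
    n_times: int = 4
    n_layers: int = 3  # fixed S/M/D
    n_asvs: int = 2000
    library_size: int = 50_000
    sad_sigma: float = 2.0
    depth_effect: float = 4.0
    depth_affected_fraction: float = 0.10
    min_effect_abundance: float = 1e-4  # plant shifts only on detectable ASVs
    time_effect: float = 0.0
    time_affected_fraction: float = 0.10
    n_modules: int = 3
    module_size: int = 10
    module_strength: float = 0.9
    module_factor_sd: float = 1.5
    module_abundance: float = 0.01  # target dataset fraction per member
    noise_sd: float = 0.5
    plot_sd: float = 0.1
    soil_noise_sd: float = 0.08  # relative (CV) noise on soil variables
    fertility_link: int = 20     # number of ASVs coupled to the fertility factor
    fertility_link_strength: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers != 3:
            raise ValidationError("n_layers is fixed at 3 (S/M/D)")
        if self.n_modules * self.module_size > self.n_asvs:
            raise ValidationError("module_size * n_modules must be <= n_asvs")
        if not (0 <= self.module_strength < 1):
            raise ValidationError("module_strength must be in [0, 1)")
        if not (0 < self.module_abundance
                and self.n_modules * self.module_size * self.module_abundance < 1):
            raise ValidationError(
                "module_abundance must be positive with total module mass < 1")
        for name in ("n_plots", "n_times", "n_asvs", "library_size"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("depth_effect", "time_effect"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0 (fold change; 0 disables)")

    @property
    def n_samples(self) -> int:
        return self.n_plots * self.n_times * self.n_layers


def simulate_dataset(params: SimulationParams):
    """Draw one dataset; deterministic for a fixed seed.

    Returns (CountTable, SampleMetadata, TaxonomyTable, SoilVariables,
    ground_truth dict). The ground truth records which ASVs carry layer and
    time shifts (and toward which level), module memberships, and the
    fertility-linked ASV set.
    """
    p = params
    rng = np.random.default_rng(p.seed)

    asv_ids = [f"ASV{i + 1:05d}" for i in range(p.n_asvs)]
    # Design grid, sample ids encode plot/time/layer.
    rows = []
    for plot in range(1, p.n_plots + 1):
        for t in range(1, p.n_times + 1):
            for layer in LAYERS:
                rows.append((f"P{plot}T{t}{layer}", plot, layer, f"T{t}"))
    meta = pd.DataFrame(rows, columns=["sample_id", "plot", "layer", "time"]
                        ).set_index("sample_id")
    n = len(meta)

    # Base log-abundance: log-normal SAD.
    base = rng.normal(0.0, p.sad_sigma, size=p.n_asvs)

    # Planted modules occupy the first n_modules*module_size ASVs and are
    # boosted into the abundant tail so they pass the network filters.
    module_of = {}
    m_total = p.n_modules * p.module_size
    if m_total:
        # Module members sit in the abundant tail (module_abundance of the
        # reads each, ~1% by default): above the 0.5% network-abundance
        # filter but not unrealistically dominant for a soil community.
        tail_mass = np.exp(base[m_total:]).sum()
        target = np.log(p.module_abundance * tail_mass
                        / (1.0 - m_total * p.module_abundance))
        base[:m_total] = rng.normal(target, 0.25, size=m_total)
        for m in range(p.n_modules):
            for j in range(m * p.module_size, (m + 1) * p.module_size):
                module_of[asv_ids[j]] = m

    # Layer-shifted ASVs: a designated fraction, each with a preferred layer.
    # Shifts are planted on non-module ASVs above the rare-abundance floor:
    # the emulated vertical structure is a property of the common/abundant
    # community (rare-tail shifts would be invisible at any library size),
    # and module blocks are kept purely correlational.
    base_frac = np.exp(base - base.max())
    base_frac = base_frac / base_frac.sum()
    eligible = np.flatnonzero((base_frac >= p.min_effect_abundance)
                              & (np.arange(p.n_asvs) >= m_total))
    n_depth = int(round(p.depth_affected_fraction * p.n_asvs)) if p.depth_effect > 0 else 0
    n_depth = min(n_depth, eligible.size)
    depth_idx = rng.choice(eligible, size=n_depth, replace=False) if n_depth else np.array([], int)
    depth_layer = rng.integers(0, 3, size=n_depth)  # index into LAYERS

    n_time = int(round(p.time_affected_fraction * p.n_asvs)) if p.time_effect > 0 else 0
    n_time = min(n_time, eligible.size)
    time_idx = rng.choice(eligible, size=n_time, replace=False) if n_time else np.array([], int)
    time_level = rng.integers(0, p.n_times, size=n_time)

    # Fertility-linked ASVs (excluding module members to keep blocks clean).
    n_link = min(p.fertility_link, p.n_asvs - m_total)
    link_idx = (m_total + rng.choice(p.n_asvs - m_total, size=n_link, replace=False)
                if n_link > 0 else np.array([], int))

    plot_effect = rng.normal(0.0, p.plot_sd, size=(p.n_plots, p.n_asvs))

    layer_index = np.array([LAYERS.index(l) for l in meta["layer"]])
    time_index = np.array([int(t[1:]) - 1 for t in meta["time"]])
    plot_index = meta["plot"].to_numpy() - 1

    # Per-sample latent fertility factor follows the depth gradient.
    fert_factor = (1.0 - layer_index) * 0.8 + rng.normal(0.0, 0.5, size=n)

    log_depth = np.log(p.depth_effect) if p.depth_effect > 0 else 0.0
    log_time = np.log(p.time_effect) if p.time_effect > 0 else 0.0

    loglam = np.tile(base, (n, 1))
    loglam += plot_effect[plot_index]
    # Effects enter as mean-zero log-fold contrasts: the preferred level is
    # depth_effect-fold above each other level, with no net latent-mass
    # shift into any one layer (which would otherwise perturb the
    # compositional denominator of every other ASV in that layer).
    if n_depth:
        match = (layer_index[:, None] == depth_layer[None, :]).astype(float)
        loglam[:, depth_idx] += log_depth * (match - 1.0 / 3.0)
    if n_time:
        match = (time_index[:, None] == time_level[None, :]).astype(float)
        loglam[:, time_idx] += log_time * (match - 1.0 / p.n_times)
    if n_link > 0 and p.fertility_link_strength > 0:
        loglam[:, link_idx] += p.fertility_link_strength * fert_factor[:, None]
    if m_total and p.module_strength > 0:
        factors = rng.normal(0.0, p.module_factor_sd, size=(n, p.n_modules))
        for m in range(p.n_modules):
            sl = slice(m * p.module_size, (m + 1) * p.module_size)
            loglam[:, sl] += p.module_strength * factors[:, m][:, None]
    loglam += rng.normal(0.0, p.noise_sd, size=loglam.shape)

    lam = np.exp(loglam - loglam.max(axis=1, keepdims=True))
    probs = lam / lam.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(p.library_size, probs[i]) for i in range(n)])

    table = CountTable(list(meta.index), asv_ids, counts)
    metadata = SampleMetadata(meta)

    taxonomy = _simulate_taxonomy(rng, asv_ids, base)
    soil = _simulate_soil(rng, meta, layer_index, fert_factor, p)

    ground_truth = {
        "depth_affected": {asv_ids[j]: LAYERS[depth_layer[k]]
                           for k, j in enumerate(depth_idx)},
        "time_affected": {asv_ids[j]: f"T{time_level[k] + 1}"
                          for k, j in enumerate(time_idx)},
        "modules": module_of,
        "fertility_linked": [asv_ids[j] for j in np.sort(link_idx)],
    }
    return table, metadata, taxonomy, soil, ground_truth


def _simulate_taxonomy(rng: np.random.Generator, asv_ids, base) -> TaxonomyTable:
    # Abundant ASVs draw dominant lineages; the rare tail mixes rare phyla
    # and partially unclassified lineages (the deep-soil "dark matter").
    order = np.argsort(base)
    lineages = {}
    n = len(asv_ids)
    for rank_pos, j in enumerate(order):
        u = rng.random()
        if rank_pos > 0.7 * n:  # abundant tail
            pool = _DOMINANT_LINEAGES if u < 0.9 else _RARE_LINEAGES
        else:
            pool = (_RARE_LINEAGES if u < 0.25
                    else _UNCLASSIFIED_LINEAGES if u < 0.45
                    else _DOMINANT_LINEAGES)
        lineages[asv_ids[j]] = pool[rng.integers(len(pool))]
    return TaxonomyTable({a: lineages[a] for a in asv_ids})


def _simulate_soil(rng, meta, layer_index, fert_factor, p: SimulationParams) -> SoilVariables:
    n = len(meta)
    data = {}
    for var, means in _SOIL_LAYER_MEANS.items():
        mu = np.array(means)[layer_index]
        noise = rng.normal(0.0, p.soil_noise_sd, size=n)
        vals = mu * (1.0 + noise)
        if var in ("TC", "TN", "DOC", "DON", "NH4", "NO3"):
            # Couple nutrients to the latent fertility factor.
            vals = vals * (1.0 + 0.05 * (fert_factor - fert_factor.mean()))
        data[var] = np.clip(vals, 0.01, None)
    df = pd.DataFrame(data, index=meta.index)
    tex = df[["clay", "silt", "sand"]]
    df[["clay", "silt", "sand"]] = tex.div(tex.sum(axis=1), axis=0) * 100.0
    return SoilVariables(df[list(SOIL_VARS)])
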
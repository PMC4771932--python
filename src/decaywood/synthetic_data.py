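"""Synthetic communities and a full mock wood-decay study.

Two sample-level generators provide ground truth for the model-selection
machinery: a neutral local community built by Hubbell's sequential urn
(immigration probability m, fundamental biodiversity number theta), and
niche communities drawn Poisson around a rank-abundance model's expected
abundances (the same error model the fitter assumes, keeping generator
and fitter conjugate).

:func:`simulate_decay_study` assembles a complete mock study at the
processed-table level: 19 parent wood samples x 3 replicates on a wood
density gradient 0.50 -> 0.15 g/cm^3, bacterial tables rarefiable to
1,080 reads and fungal to 2,000 reads per replicate, bacterial richness
rising as density falls, each fungal sample dominated by one phylotype,
stage-indicator taxa, planted genus-genus correlations, and metadata
with stage-dependent covariate means. Early-stage bacterial communities
are generated neutrally and middle/late ones from niche models, so the
study carries a known per-sample assembly mechanism.

Community identity across samples comes from a rank-to-taxon mapping:
rank r of a sample in stage s is assigned taxon ``BacOTU_{r + offset_s}``
with a stage-dependent offset. Replicates and same-stage parents thus
share taxa (low within-stage Bray-Curtis dissimilarity) while stages are
shifted against each other (high between-stage dissimilarity), without
distorting any sample's rank-abundance distribution.

Randomness: one global seed expands to per-sample substreams through
``numpy.random.SeedSequence(seed, spawn_key=(stream_index,))`` where the
stream index is a documented per-sample counter - any single sample can
be regenerated in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from decaywood.sad_assembly import RankAbundance, expected_abundance
from decaywood.tables_io import CountMatrix, SampleMetadata, TaxonomyMap


@dataclass
class NeutralParams:
    """Hubbell neutral local-community parameters."""
    theta: float   # fundamental biodiversity number, > 0
    m: float       # immigration probability, 0 < m <= 1
    J: int         # local community size (individuals)

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if not 0 < self.m <= 1:
            raise ValueError("m must be in (0, 1]")
        if self.J < 1:
            raise ValueError("J must be >= 1")

    @property
    def I(self) -> float:
        """Immigration parameter I = m(J-1)/(1-m); inf at m = 1."""
        if self.m == 1.0:
            return math.inf
        return self.m * (self.J - 1) / (1.0 - self.m)


@dataclass
class NicheParams:
    """A niche rank-abundance model plus sampling dimensions."""
    model: str
    params: dict[str, float]
    S: int
    J: int

    def __post_init__(self) -> None:
        if self.S < 1 or self.J < 1:
            raise ValueError("S and J must be >= 1")
        # validates model name and parameter domains
        expected_abundance(self.model, self.params, self.S, self.J)


def simulate_neutral_sample(p: NeutralParams, seed) -> RankAbundance:
    """Draw one local community by the sequential neutral urn.

    Individual j (1-based) is an immigrant with probability
    I/(I + j - 1), else copies the species of a uniformly chosen earlier
    individual. Immigrant ancestry follows a Ewens(theta) urn over
    immigration events: a new metacommunity species appears with
    probability theta/(theta + k) after k prior immigration events. At
    m = 1 every individual is an immigrant and the sample is exactly
    Ewens(theta).
    """
    rng = np.random.default_rng(seed)
    J = p.J
    inf_I = math.isinf(p.I)
    species_of: list[int] = []         # species index per individual
    immigrant_species: list[int] = []  # species per immigration event
    n_species = 0
    for j in range(J):
        # the first individual is always an immigrant (I/(I+0) -> 1)
        if j == 0 or inf_I or rng.random() < p.I / (p.I + j):
            k = len(immigrant_species)
            if rng.random() < p.theta / (p.theta + k):
                sp = n_species
                n_species += 1
            else:
                sp = immigrant_species[rng.integers(k)]
            immigrant_species.append(sp)
        else:
            sp = species_of[rng.integers(j)]
        species_of.append(sp)
    counts = np.bincount(species_of, minlength=n_species)
    return RankAbundance(counts[counts > 0])


def simulate_niche_sample(p: NicheParams, seed) -> RankAbundance:
    """Poisson sample around a niche model's expected abundances.

    Expected abundances are rescaled to sum to J before sampling, then
    each rank draws independently Poisson(lambda_r); zero draws drop out.
    """
    rng = np.random.default_rng(seed)
    lam = expected_abundance(p.model, p.params, p.S, p.J)
    lam = lam * (p.J / lam.sum())
    draw = rng.poisson(lam)
    if not (draw > 0).any():  # keep at least the dominant rank occupied
        draw[0] = 1
    return RankAbundance(draw[draw > 0])


# ---------------------------------------------------------------------------
# Full decay-gradient study

@dataclass
class StudyConfig:
    """Knobs of the mock decay study (defaults mirror the field study)."""

    n_parents: int = 19
    reps: int = 3
    density_high: float = 0.50
    density_low: float = 0.15
    # stage bands in g/cm^3: early > band_early, late < band_late
    band_early: float = 0.40
    band_late: float = 0.30
    bacterial_depth: int = 1080
    fungal_depth: int = 2000
    depth_margin: float = 1.25     # generated reads ~= depth * margin
    # bacterial richness target S(density): rises as wood density falls.
    # The early stage's richness follows from (theta, m, J) instead
    # (~80 observed species at depth 1080); the gradient places the
    # niche stages above it so observed richness rises through decay.
    richness_at_high_density: int = 95
    richness_at_low_density: int = 150
    richness_noise_sd: float = 6.0
    # assembly mechanism planted per stage (bacteria)
    early_neutral_theta: float = 30.0
    early_neutral_m: float = 0.2
    niche_model_middle: str = "zipf"
    niche_params_middle: dict = field(
        default_factory=lambda: {"p1": 0.2, "gamma": -0.9})
    niche_model_late: str = "zipf"
    niche_params_late: dict = field(
        default_factory=lambda: {"p1": 0.2, "gamma": -0.9})
    # stage offsets of the rank-to-taxon mapping (community contrast)
    stage_offsets: dict = field(default_factory=lambda: {
        "early": 0, "middle": 60, "late": 120})
    # fungal community: dominant phylotype share and tail richness
    fungal_dominant_share: float = 0.6
    fungal_richness: int = 40
    # planted genus-genus correlations: (genus_a, genus_b, rho)
    correlated_pairs: tuple = (
        ("BacGenusCorrA1", "BacGenusCorrA2", 0.95),
        ("BacGenusCorrB1", "BacGenusCorrB2", -0.9),
        ("BacGenusCorrC1", "FunGenusCorrC2", 0.9),
    )
    pair_base_share: float = 0.01  # mean relative abundance of pair taxa
    pair_response: float = 0.7     # abundance slope on the latent field
    # stage-indicator taxa: genus -> stage it is confined to
    indicator_taxa: dict = field(default_factory=lambda: {
        "BacGenusEarlyMark": "early",
        "BacGenusMiddleMark": "middle",
        "BacGenusLateMark": "late",
    })
    indicator_share: float = 0.006
    # per-stage covariate means (early, middle, late) and within-stage sd
    ph_means: tuple = (4.90, 3.96, 4.16)
    ph_sd: float = 0.12
    moisture_means: tuple = (31.62, 33.34, 138.99)
    moisture_sd: float = 2.5
    cn_means: tuple = (1009.25, 743.02, 267.30)
    cn_sd: float = 80.0
    ergosterol_means: tuple = (14.19, 41.98, 46.13)
    ergosterol_sd: float = 2.0

    def stage_of(self, density: float) -> str:
        if density > self.band_early:
            return "early"
        if density >= self.band_late:
            return "middle"
        return "late"

    def validate(self) -> None:
        if not (self.density_low < self.band_late
                <= self.band_early < self.density_high):
            raise ValueError(
                "stage bands must fall inside the density gradient: need "
                f"{self.density_low} < {self.band_late} <= "
                f"{self.band_early} < {self.density_high}")


# per-sample stream indices (documented counter scheme)
_STREAM_META = 0
_STREAM_BACTERIA = 1000
_STREAM_FUNGI = 2000
_STREAM_PAIRS = 3000


def _substream(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def simulate_decay_study(n_parents: int = 19, reps: int = 3, seed: int = 0,
                         config: StudyConfig | None = None):
    """Generate a complete mock decay study.

    Returns ``(bacteria, fungi, taxonomy, metadata, truth)``: two
    :class:`CountMatrix` with one row per replicate, the taxonomy map,
    per-replicate metadata, and a ground-truth manifest dict (per-parent
    stage and generating model, planted correlations and indicators).
    """
    cfg = config or StudyConfig()
    if config is None:
        cfg.n_parents, cfg.reps = n_parents, reps
    cfg.validate()
    cfg_n, cfg_r = cfg.n_parents, cfg.reps

    densities = np.linspace(cfg.density_high, cfg.density_low, cfg_n)
    parents = [f"Pi{i + 1:02d}" for i in range(cfg_n)]
    stages = [cfg.stage_of(d) for d in densities]

    # latent per-parent fields driving the planted correlated genus pairs;
    # abundance responds linearly so negative correlations survive the map
    pair_rng = _substream(seed, _STREAM_PAIRS)
    pair_profiles: dict[str, np.ndarray] = {}
    for ga, gb, rho in cfg.correlated_pairs:
        z1 = pair_rng.normal(size=cfg_n)
        z2 = rho * z1 + math.sqrt(max(0.0, 1 - rho * rho)) * \
            pair_rng.normal(size=cfg_n)
        pair_profiles[ga] = z1
        pair_profiles[gb] = z2

    bac_rows: dict[str, dict[str, int]] = {}
    fun_rows: dict[str, dict[str, int]] = {}
    meta_rows = []
    truth_samples = {}

    stage_idx = {"early": 0, "middle": 1, "late": 2}
    meta_rng = _substream(seed, _STREAM_META)

    for pi, (parent, dens, stage) in enumerate(zip(parents, densities, stages)):
        si = stage_idx[stage]
        frac = (cfg.density_high - dens) / (cfg.density_high - cfg.density_low)
        s_mean = (cfg.richness_at_high_density
                  + frac * (cfg.richness_at_low_density
                            - cfg.richness_at_high_density))
        ph = meta_rng.normal(cfg.ph_means[si], cfg.ph_sd)
        moist = max(0.0, meta_rng.normal(cfg.moisture_means[si],
                                         cfg.moisture_sd))
        cn = max(1.0, meta_rng.normal(cfg.cn_means[si], cfg.cn_sd))
        ergo = max(0.0, meta_rng.normal(cfg.ergosterol_means[si],
                                        cfg.ergosterol_sd))
        truth_samples[parent] = {
            "stage": stage, "density": float(dens),
            "bacterial_mechanism": "neutral" if stage == "early" else "niche",
            "bacterial_model": ("zsm" if stage == "early"
                                else cfg.niche_model_middle
                                if stage == "middle"
                                else cfg.niche_model_late),
        }
        for r in range(cfg_r):
            sid = f"{parent}_r{r + 1}"
            rep_counter = pi * cfg_r + r
            # --- bacteria
            brng = _substream(seed, _STREAM_BACTERIA + rep_counter)
            j_bac = int(round(cfg.bacterial_depth * cfg.depth_margin))
            if stage == "early":
                ra = simulate_neutral_sample(
                    NeutralParams(cfg.early_neutral_theta,
                                  cfg.early_neutral_m, j_bac), brng)
            else:
                s_rep = max(8, int(round(
                    brng.normal(s_mean, cfg.richness_noise_sd))))
                model = (cfg.niche_model_middle if stage == "middle"
                         else cfg.niche_model_late)
                params = (cfg.niche_params_middle if stage == "middle"
                          else cfg.niche_params_late)
                ra = simulate_niche_sample(
                    NicheParams(model, dict(params), s_rep, j_bac), brng)
            offset = cfg.stage_offsets[stage]
            counts = {f"BacOTU{offset + k:04d}": int(v)
                      for k, v in enumerate(ra.abundances)}
            counts = _with_indicators(counts, cfg, stage, j_bac, brng)
            counts = _with_pairs(counts, cfg, pair_profiles, pi, j_bac,
                                 brng, kingdom="Bac")
            bac_rows[sid] = counts
            # --- fungi
            frng = _substream(seed, _STREAM_FUNGI + rep_counter)
            j_fun = int(round(cfg.fungal_depth * cfg.depth_margin))
            fun_counts = _fungal_sample(cfg, parent, j_fun, frng)
            fun_counts = _with_pairs(fun_counts, cfg, pair_profiles, pi,
                                     j_fun, frng, kingdom="Fun")
            fun_rows[sid] = fun_counts
            meta_rows.append({
                "sample_id": sid, "wood_density": float(dens),
                "pH": float(ph), "moisture": float(moist),
                "c_n_ratio": float(cn), "ergosterol": float(ergo),
                "replicate_of": parent,
            })

    bacteria = _rows_to_matrix(bac_rows)
    fungi = _rows_to_matrix(fun_rows)
    taxonomy = _make_taxonomy(bacteria.taxon_ids, fungi.taxon_ids)
    meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    truth = {
        "seed": int(seed),
        "generators": {
            "early": {"model": "zsm", "theta": cfg.early_neutral_theta,
                      "m": cfg.early_neutral_m},
            "middle": {"model": cfg.niche_model_middle,
                       **cfg.niche_params_middle},
            "late": {"model": cfg.niche_model_late,
                     **cfg.niche_params_late},
        },
        "samples": truth_samples,
        "correlated_pairs": [list(p) for p in cfg.correlated_pairs],
        "indicator_taxa": dict(cfg.indicator_taxa),
        "stage_bands": {"early_above": cfg.band_early,
                        "late_below": cfg.band_late},
    }
    return bacteria, fungi, taxonomy, meta, truth


def _with_indicators(counts: dict[str, int], cfg: StudyConfig, stage: str,
                     j: int, rng: np.random.Generator) -> dict[str, int]:
    for genus, target_stage in cfg.indicator_taxa.items():
        if stage == target_stage:
            v = rng.poisson(cfg.indicator_share * j)
            if v > 0:
                key = f"OTU_{genus}"
                counts[key] = counts.get(key, 0) + int(v)
    return counts


def _with_pairs(counts: dict[str, int], cfg: StudyConfig,
                profiles: dict[str, np.ndarray], parent_index: int,
                j: int, rng: np.random.Generator,
                kingdom: str) -> dict[str, int]:
    for genus, z in profiles.items():
        if not genus.startswith(kingdom):
            continue
        lam = cfg.pair_base_share * j * max(
            0.05, 1.0 + cfg.pair_response * float(z[parent_index]))
        v = rng.poisson(lam)
        if v > 0:
            key = f"OTU_{genus}"
            counts[key] = counts.get(key, 0) + int(v)
    return counts


def _fungal_sample(cfg: StudyConfig, parent: str, j: int,
                   rng: np.random.Generator) -> dict[str, int]:
    """One fungal replicate: a single dominant phylotype plus a tail.

    The dominant phylotype is parent-specific (each wood sample has its
    own fungal signature); the geometric tail is shared.
    """
    s = cfg.fungal_richness
    tail = np.exp(-0.25 * np.arange(s - 1))
    lam = np.r_[cfg.fungal_dominant_share,
                (1 - cfg.fungal_dominant_share) * tail / tail.sum()] * j
    draw = rng.poisson(lam)
    draw[0] = max(int(draw[0]), int(math.ceil(0.5 * j)) + 1)  # dominance
    out = {f"FunOTU_{parent}_dom": int(draw[0])}
    for k, v in enumerate(draw[1:]):
        if v > 0:
            out[f"FunOTU_tail{k:03d}"] = int(v)
    return out


def _rows_to_matrix(rows: dict[str, dict[str, int]]) -> CountMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(np.int64)
    return CountMatrix(df[sorted(df.columns)])


def _make_taxonomy(bac_taxa, fun_taxa) -> TaxonomyMap:
    lineages = {}
    for tid in bac_taxa:
        genus = _genus_from_otu(tid)
        lineages[tid] = {
            "kingdom": "Bacteria", "phylum": "SynthPhylum",
            "class": "SynthClass", "order": f"Order_{genus[:12]}",
            "family": f"Family_{genus}", "genus": genus,
        }
    for tid in fun_taxa:
        genus = _genus_from_otu(tid)
        lineages[tid] = {
            "kingdom": "Fungi", "phylum": "SynthMycota",
            "class": "SynthMycetes", "order": f"Order_{genus[:12]}",
            "family": f"Family_{genus}", "genus": genus,
        }
    return TaxonomyMap(lineages)


def _genus_from_otu(tid: str) -> str:
    """OTU id -> genus name (planted taxa keep their genus label)."""
    if tid.startswith("OTU_"):
        return tid[4:]
    if tid.endswith("_dom"):
        return "FunDominant_" + tid.split("_")[1]
    if "tail" in tid:
        return "FunTail" + tid.split("tail")[1]
    # pool-taxon OTUs: one genus per OTU (fine-grained)
    return "Genus_" + tid
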
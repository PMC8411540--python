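"""Synthetic cohort generator with planted ground truth.

Emulates the five inputs the analysis consumes — reference-coordinate
genomes, strain metadata, gene presence/absence, gene annotations, and
sample x taxon abundances — with the structure the downstream stages assume:
divergent populations, clonal expansions at two SNP scales, high-density
recombination imports, population-specific accessory genes, an
age-associated SNP triplet, and abundance tables with geography/age effects.

The genome model is star-like: a shared reference ancestor, one ancestor
branch per population (length ``pop_divergence_scale x mutation_scale``
expected substitutions/site), and independent tip branches (length
``mutation_scale``).  Recombination imports are modeled as tracts of
elevated mutation density (background x multiplier), which is exactly the
signal the downstream masking stage detects; no donor-sequence copying is
performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .coresnp import AlignedGenomeSet
from .errors import ConfigError
from .io import COG_ALPHABET

REFERENCE_ID = "reference"
FOCAL_TAXON = "Bifidobacterium"

#: KEGG pathway planted as enriched among population-specific genes.
PLANTED_PATHWAY = "ko00520"
#: COG category planted as enriched (carbohydrate transport and metabolism).
PLANTED_COG = "G"


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort; ``seed`` fixes every output bit-for-bit."""

    seed: int = 0
    genome_length: int = 50_000
    n_populations: int = 3
    strains_per_population: int = 20
    #: expected substitutions per site on each tip branch
    mutation_scale: float = 0.006
    #: population ancestor branch, as a multiple of mutation_scale
    #: (2.0 gives between:within pairwise divergence of 3:1)
    pop_divergence_scale: float = 2.0
    #: (size, max_pairwise_snps) per planted clonal expansion
    clone_groups: tuple[tuple[int, int], ...] = ((2, 8), (2, 8))
    #: (length_bp, density_multiplier) tracts planted once per strain each
    import_tracts: tuple[tuple[int, float], ...] = ()
    causal_snp_effect: float = 40.0
    causal_snp_count: int = 3
    age_baseline: float = 20.0
    age_noise_sd: float = 5.0
    carrier_fraction: float = 0.4
    pop_specific_genes: int = 5
    province_leakage: float = 0.05
    n_background_genes: int = 40
    n_noise_genes: int = 30
    n_taxa: int = 12
    abundance_depth: int = 50_000
    dirichlet_concentration: float = 200.0
    abundance_effects: dict = field(
        default_factory=lambda: {"age_slope": -0.02, "province_sd": 0.5})

    def validate(self) -> None:
        if self.genome_length < 1000:
            raise ConfigError("genome_length must be >= 1000")
        for name in ("n_populations", "strains_per_population", "causal_snp_count",
                     "pop_specific_genes", "n_taxa"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.mutation_scale < 0:
            raise ConfigError("mutation_scale must be >= 0")
        per_pop = [0] * max(self.n_populations, 1)
        for g, (size, max_snps) in enumerate(self.clone_groups):
            if size < 2:
                raise ConfigError(f"clone_groups[{g}]: size must be >= 2")
            if max_snps < 0:
                raise ConfigError(f"clone_groups[{g}]: max_pairwise_snps must be >= 0")
            per_pop[g % max(self.n_populations, 1)] += size
        if any(c > self.strains_per_population for c in per_pop):
            raise ConfigError(
                "clone_groups: total clone members exceed strains_per_population "
                "in at least one population")
        for t, (length, mult) in enumerate(self.import_tracts):
            if not 0 < length <= self.genome_length:
                raise ConfigError(f"import_tracts[{t}]: length outside (0, genome_length]")
            if mult < 1:
                raise ConfigError(f"import_tracts[{t}]: density multiplier must be >= 1")


@dataclass
class SimTruth:
    """Planted ground truth for every downstream stage."""

    population_of: dict[str, str]
    clone_group_of: dict[str, str]
    #: strain -> list of 0-based half-open [start, end) bp intervals
    import_intervals: dict[str, list[tuple[int, int]]]
    #: 1-based reference positions of planted phenotype-associated SNPs
    causal_sites: list[int]
    #: strain -> 0/1 carriage of the causal allele triplet
    causal_carriers: dict[str, int]
    gene_population_map: dict[str, str] = field(default_factory=dict)
    covariate_effects: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float,
            lo: int = 0, hi: int | None = None) -> np.ndarray:
    """Per-site substitution with probability ``rate`` on [lo, hi)."""
    out = codes.copy()
    hi = codes.size if hi is None else hi
    span = hi - lo
    if rate <= 0 or span <= 0:
        return out
    hit = np.flatnonzero(rng.random(span) < rate) + lo
    out[hit] = (out[hit] + rng.integers(1, 4, hit.size)) % 4
    return out


def _mutate_exact(rng: np.random.Generator, codes: np.ndarray, n: int) -> np.ndarray:
    out = codes.copy()
    if n <= 0:
        return out
    hit = rng.choice(codes.size, size=n, replace=False)
    out[hit] = (out[hit] + rng.integers(1, 4, n)) % 4
    return out


def simulate_genomes(config: SimConfig) -> tuple[AlignedGenomeSet, SimTruth]:
    """Generate the aligned cohort genomes and the planted-truth record."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    L = config.genome_length
    ref = rng.integers(0, 4, L).astype(np.int8)

    population_of: dict[str, str] = {}
    clone_group_of: dict[str, str] = {}
    import_intervals: dict[str, list[tuple[int, int]]] = {}
    ids: list[str] = []
    rows: list[np.ndarray] = []

    # clone groups are distributed round-robin over populations
    clones_in_pop: dict[int, list[tuple[str, int, int]]] = {}
    for g, (size, max_snps) in enumerate(config.clone_groups):
        clones_in_pop.setdefault(g % config.n_populations, []).append(
            (f"cg{g + 1}", size, max_snps))

    for p in range(config.n_populations):
        pop_label = f"pop{p + 1}"
        ancestor = _mutate(rng, ref, config.mutation_scale * config.pop_divergence_scale)
        slots = config.strains_per_population
        regular = slots - sum(size for _, size, _ in clones_in_pop.get(p, []))
        idx = 0
        for _ in range(regular):
            idx += 1
            sid = f"p{p + 1}s{idx:02d}"
            ids.append(sid)
            rows.append(_mutate(rng, ancestor, config.mutation_scale))
            population_of[sid] = pop_label
        for gid, size, max_snps in clones_in_pop.get(p, []):
            clone_ancestor = _mutate(rng, ancestor, config.mutation_scale)
            per_member = max_snps // 2
            for _ in range(size):
                idx += 1
                sid = f"p{p + 1}s{idx:02d}"
                ids.append(sid)
                rows.append(_mutate_exact(rng, clone_ancestor, per_member))
                population_of[sid] = pop_label
                clone_group_of[sid] = gid

    # recombination imports: one tract per (strain, tract spec), random location
    for i, sid in enumerate(ids):
        tracts = []
        for length, mult in config.import_tracts:
            start = int(rng.integers(0, L - length + 1))
            rows[i] = _mutate(rng, rows[i], config.mutation_scale * (mult - 1.0),
                              lo=start, hi=start + length)
            tracts.append((start, start + length))
        import_intervals[sid] = tracts

    # phenotype-associated SNP triplet: carriers get the alt base at every
    # causal site, non-carriers the reference base (overwrites any mutation)
    causal_sites: list[int] = []
    causal_carriers = {sid: 0 for sid in ids}
    if config.causal_snp_count > 0 and ids:
        pos0 = np.sort(rng.choice(L, config.causal_snp_count, replace=False))
        causal_sites = [int(p) + 1 for p in pos0]
        carriers = rng.random(len(ids)) < config.carrier_fraction
        if carriers.all():
            carriers[0] = False
        if not carriers.any():
            carriers[0] = True
        for i, sid in enumerate(ids):
            causal_carriers[sid] = int(carriers[i])
            for p in pos0:
                rows[i][p] = (ref[p] + 1) % 4 if carriers[i] else ref[p]

    genomes = AlignedGenomeSet([REFERENCE_ID] + ids, REFERENCE_ID,
                               np.vstack([ref] + rows) if ids else ref[None, :])
    truth = SimTruth(population_of, clone_group_of, import_intervals,
                     causal_sites, causal_carriers,
                     covariate_effects={"causal_snp_effect": config.causal_snp_effect,
                                        **config.abundance_effects})
    return genomes, truth


def simulate_metadata_and_genes(
    truth: SimTruth, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate strain metadata, the gene presence/absence matrix, and annotations.

    Age = baseline + effect x causal-allele + Gaussian noise.  Provinces map
    1:1 to populations with ``province_leakage`` random reassignment; clone
    group members share a household (family/community/city) so that planted
    transmission events are classifiable from metadata alone.
    """
    rng = np.random.default_rng([config.seed, 1])
    strains = list(truth.population_of)
    pops = sorted({truth.population_of[s] for s in strains})
    province_of_pop = {p: f"province{i + 1}" for i, p in enumerate(pops)}
    longevous = {prov for i, prov in enumerate(province_of_pop.values()) if i % 2 == 1}

    records = []
    clone_first: dict[str, dict] = {}
    for i, sid in enumerate(strains):
        prov = province_of_pop[truth.population_of[sid]]
        if rng.random() < config.province_leakage and len(pops) > 1:
            others = [v for v in province_of_pop.values() if v != prov]
            prov = others[int(rng.integers(len(others)))]
        city = f"{prov}-city{int(rng.integers(2)) + 1}"
        community = f"{city}-com{int(rng.integers(2)) + 1}"
        rec = {
            "strain_id": sid,
            "sample_id": f"samp{i + 1:03d}",
            "country": "countryA" if prov in list(province_of_pop.values())[:2] else "countryB",
            "province": prov,
            "city": city,
            "community_id": community,
            "family_id": f"fam{i + 1:03d}",
            "host_species": "human",
            "age": max(0.0, config.age_baseline
                       + config.causal_snp_effect * truth.causal_carriers[sid]
                       + rng.normal(0.0, config.age_noise_sd)),
            "sex": "male" if rng.random() < 0.5 else "female",
            "longevous_district": prov in longevous,
        }
        gid = truth.clone_group_of.get(sid)
        if gid is not None:
            if gid in clone_first:  # share the first member's household
                first = clone_first[gid]
                for key in ("country", "province", "city", "community_id", "family_id"):
                    rec[key] = first[key]
            else:
                clone_first[gid] = rec
        records.append(rec)
    meta = pd.DataFrame(records).set_index("strain_id", drop=False)

    # gene presence/absence: universal core + random-carriage noise +
    # deterministic population-specific genes (100% own population, 0% others)
    gene_rows: dict[str, np.ndarray] = {}
    n = len(strains)
    for g in range(config.n_background_genes):
        gene_rows[f"core{g + 1:04d}"] = np.ones(n, dtype=bool)
    for g in range(config.n_noise_genes):
        frac = rng.uniform(0.2, 0.8)
        gene_rows[f"acc{g + 1:04d}"] = rng.random(n) < frac
    pop_arr = np.array([truth.population_of[s] for s in strains])
    for p in pops:
        for g in range(config.pop_specific_genes):
            gid = f"psg_{p}_{g + 1:02d}"
            gene_rows[gid] = pop_arr == p
            truth.gene_population_map[gid] = p
    presence = pd.DataFrame(gene_rows, index=strains).T

    # annotations: genes tile the reference; population-specific genes are
    # biased into one COG category and one pathway to plant enrichment signal
    kegg_pool = [f"ko{(i + 1) * 10:05d}" for i in range(200)]
    ann_records = []
    for k, gid in enumerate(presence.index):
        planted = gid in truth.gene_population_map
        if planted and rng.random() < 0.8:
            cog, kegg = PLANTED_COG, PLANTED_PATHWAY
        else:
            cog = COG_ALPHABET[int(rng.integers(len(COG_ALPHABET)))]
            kegg = kegg_pool[int(rng.integers(len(kegg_pool)))]
        start = (k * 1000) % max(config.genome_length - 1000, 1) + 1
        ann_records.append({"gene_id": gid, "cog": cog, "kegg": kegg,
                            "start": start, "end": start + 899})
    annotation = pd.DataFrame(ann_records).set_index("gene_id", drop=False)
    return meta, presence, annotation


def simulate_abundance(config: SimConfig, metadata: pd.DataFrame) -> pd.DataFrame:
    """Dirichlet-multinomial sample x taxon counts with planted covariate effects.

    The focal taxon's expected relative abundance decreases monotonically in
    age (log-linear with slope ``abundance_effects['age_slope']`` per year);
    province shifts the baseline composition of every taxon.
    """
    rng = np.random.default_rng([config.seed, 2])
    n_taxa = max(config.n_taxa, 1)
    taxa = [FOCAL_TAXON] + [f"taxon{i:02d}" for i in range(2, n_taxa + 1)]
    base = rng.normal(0.0, 1.0, n_taxa)
    base[0] += 1.0  # focal taxon starts dominant
    provinces = sorted(metadata["province"].dropna().unique())
    prov_shift = {
        p: rng.normal(0.0, config.abundance_effects.get("province_sd", 0.0), n_taxa)
        for p in provinces
    }
    age_slope = config.abundance_effects.get("age_slope", 0.0)

    counts = np.zeros((len(metadata), n_taxa), dtype=np.int64)
    for i, (_, row) in enumerate(metadata.iterrows()):
        logits = base + prov_shift.get(row["province"], 0.0)
        logits = logits.copy()
        logits[0] += age_slope * float(row["age"])
        p = np.exp(logits - logits.max())
        p /= p.sum()
        q = rng.dirichlet(config.dirichlet_concentration * p)
        counts[i] = rng.multinomial(config.abundance_depth, q)
    return pd.DataFrame(counts, index=metadata["sample_id"].to_numpy(), columns=taxa)


def simulate_cohort(config: SimConfig):
    """Run all three generators; returns (genomes, truth, metadata, presence, annotation, abundance)."""
    genomes, truth = simulate_genomes(config)
    meta, presence, annotation = simulate_metadata_and_genes(truth, config)
    abundance = simulate_abundance(config, meta)
    return genomes, truth, meta, presence, annotation, abundance
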
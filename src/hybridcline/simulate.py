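"""Forward-time individual-based simulation of a linear hybrid zone.

The model: ``n_demes`` demes arrayed on a one-dimensional transect, each with
carrying capacity ``K``, non-overlapping generations and random mating between
hermaphroditic adults within a deme (selfing allowed).  A single quantitative
trait is controlled additively by ``n_trait_loci`` bi-allelic loci with
allelic effects -1/+1; a further ``n_neutral_loci`` bi-allelic loci segregate
neutrally.  The trait optimum varies clinally across demes and fitness is
Gaussian stabilizing selection around the local optimum,

    W = exp(-(P - Z_opt)^2 / (2 * omega^2)),

with selection acting on fecundity: parents are sampled with replacement
proportionally to W.  Phenotypes are P = G + e where the environmental
variance is set each generation from the metapopulation genetic variance so
that heritability stays at the configured value.  Migration is either
stepping-stone (neighbouring demes only) or island (any other deme).

The simulation is initialized as a secondary-contact scenario: the demes at
one end are fixed for alleles representative of one parental species, the
demes at the other end for the alternative alleles, and the central demes are
empty and become colonized through migration.

Because all loci are bi-allelic and unlinked, the internal state stores the
per-individual dosage (0/1/2 copies of allele 1) per locus; a parent with
dosage g transmits allele 1 with probability g/2, which is exactly Mendelian
transmission for exchangeable allele copies.  Snapshots expand dosages back
to explicit allele pairs.

This module doubles as the package's synthetic-data generator:
:func:`make_fixture_dataset` builds a 13-population transect dataset (SSRs,
SNPs and climate metadata) emulating a wide spruce hybrid zone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

log = logging.getLogger(__name__)

DEFAULT_TRAIT_OPTIMA = (-5.0, -5.0, -4.0, -2.0, 0.0, 2.0, 4.0, 5.0, 5.0)


class ConfigurationError(ValueError):
    """Invalid simulation parameterization."""


@dataclass
class SimulationConfig:
    """Parameters of the hybrid-zone simulation.

    Defaults describe the 9-deme secondary-contact scenario: K=1000,
    clinal trait optima (-5,-5,-4,-2,0,2,4,5,5), 40 trait + 40 neutral
    bi-allelic loci, allelic effects -1/+1, heritability 0.5 and
    stabilizing-selection intensity omega=10.  The migration rate is not
    pinned by the scenario; 0.05 is the package default.
    """

    n_demes: int = 9
    carrying_capacity: int = 1000
    migration_rate: float = 0.05
    migration_model: str = "stepping_stone"  # or "island"
    n_trait_loci: int = 40
    n_neutral_loci: int = 40
    allelic_effects: tuple[float, float] = (-1.0, 1.0)
    trait_optima: tuple[float, ...] = DEFAULT_TRAIT_OPTIMA
    omega: float = 10.0
    heritability: float = 0.5
    n_generations: int = 100
    seed: int = 0
    snapshot_generations: tuple[int, ...] = ()
    summary_every: int = 0  # 0: record summaries only at snapshots + final

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if len(self.trait_optima) != self.n_demes:
            raise ConfigurationError(
                f"trait_optima has {len(self.trait_optima)} entries for "
                f"{self.n_demes} demes")
        if self.carrying_capacity < 2:
            raise ConfigurationError("carrying_capacity must be >= 2")
        if not 0.0 <= self.migration_rate <= 0.5:
            raise ConfigurationError("migration_rate must lie in [0, 0.5]")
        if self.migration_model not in ("stepping_stone", "island"):
            raise ConfigurationError(
                f"unknown migration model {self.migration_model!r}")
        if self.omega <= 0:
            raise ConfigurationError("omega must be positive")
        if not 0.0 < self.heritability <= 1.0:
            raise ConfigurationError("heritability must lie in (0, 1]")
        if self.n_trait_loci < 0 or self.n_neutral_loci < 0:
            raise ConfigurationError("locus counts must be non-negative")

    @property
    def n_loci(self) -> int:
        return self.n_trait_loci + self.n_neutral_loci


@dataclass
class SimState:
    """Per-generation state: all living individuals across demes.

    ``dosage[i, l]`` is the number of copies of allele 1 (the allele
    representative of the second parental species) carried by individual
    ``i`` at locus ``l``; the first ``n_trait_loci`` columns are trait loci.
    """

    generation: int
    deme: np.ndarray      # (N,) deme index per individual
    dosage: np.ndarray    # (N, L) int8 in {0, 1, 2}
    G: np.ndarray         # (N,) genetic value
    P: np.ndarray         # (N,) phenotype
    W: np.ndarray         # (N,) fitness in (0, 1]

    @property
    def n_individuals(self) -> int:
        return self.deme.shape[0]

    def deme_sizes(self, n_demes: int) -> np.ndarray:
        return np.bincount(self.deme, minlength=n_demes)

    def rows_in_demes(self, demes) -> np.ndarray:
        return np.where(np.isin(self.deme, np.atleast_1d(demes)))[0]


@dataclass
class SimResult:
    """Snapshots and per-generation summaries of a run."""

    config: SimulationConfig
    snapshots: list[tuple[int, GenotypeMatrix]]
    summary: pd.DataFrame
    final_state: SimState = None


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def fitness(P, Zopt, omega):
    """Gaussian stabilizing-selection fitness around the local optimum.

    ``W = exp(-(P - Zopt)^2 / (2 omega^2))``: equals 1 at the optimum and
    decreases strictly with |P - Zopt|; omega sets how quickly.
    """
    if omega <= 0:
        raise ConfigurationError("omega must be positive")
    P = np.asarray(P, dtype=float)
    return np.exp(-((P - Zopt) ** 2) / (2.0 * omega ** 2))


def genetic_value(genotype_row, effects=(-1.0, 1.0)):
    """Additive genetic value: sum of allelic effects over all allele copies.

    ``genotype_row`` is an ``(L, 2)`` array of allele codes in {0, 1} at the
    trait loci.  Missing alleles are an error: simulated data are complete.
    """
    g = np.asarray(genotype_row)
    if np.any(g < 0):
        raise ValueError("missing allele in trait genotype")
    e0, e1 = effects
    n_ones = int(g.sum())
    return e1 * n_ones + e0 * (g.size - n_ones)


def _genetic_values_from_dosage(dosage, n_trait_loci, effects):
    if n_trait_loci == 0:
        return np.zeros(dosage.shape[0])
    e0, e1 = effects
    s = dosage[:, :n_trait_loci].sum(axis=1, dtype=np.int64)
    return e1 * s + e0 * (2 * n_trait_loci - s)


def assign_phenotypes(G, h2, rng):
    """Phenotypes P = G + e with environmental variance from heritability.

    The environmental variance is V_E = V_G (1 - h2) / h2 where V_G is the
    metapopulation variance of G this generation, so realized heritability
    Var(G)/Var(P) stays at h2.  When V_G is zero, P = G.
    """
    G = np.asarray(G, dtype=float)
    if G.size == 0:
        raise ValueError("no individuals")
    vg = G.var()
    if vg == 0.0 or h2 >= 1.0:
        return G.copy()
    ve = vg * (1.0 - h2) / h2
    return G + rng.normal(0.0, np.sqrt(ve), size=G.size)


def _assign_phenotype_fitness(state: SimState, config: SimulationConfig,
                              rng) -> None:
    state.G = _genetic_values_from_dosage(
        state.dosage, config.n_trait_loci, config.allelic_effects)
    state.P = assign_phenotypes(state.G, config.heritability, rng)
    zopt = np.asarray(config.trait_optima, dtype=float)[state.deme]
    state.W = fitness(state.P, zopt, config.omega)


def migrate(state: SimState, m: float, model: str, rng,
            n_demes: int) -> SimState:
    """Relocate each individual with probability ``m``.

    Stepping-stone: destination is a uniformly chosen adjacent deme (edge
    demes have a single neighbour).  Island: destination uniform over all
    other demes.  Individual count is conserved; empty demes can receive
    migrants (colonization).
    """
    if m == 0.0 or state.n_individuals == 0:
        return state
    move = rng.random(state.n_individuals) < m
    idx = np.where(move)[0]
    if idx.size == 0:
        return state
    deme = state.deme.copy()
    src = deme[idx]
    if model == "stepping_stone":
        dest = src + (rng.integers(0, 2, idx.size) * 2 - 1)
        dest[dest < 0] = 1
        dest[dest >= n_demes] = n_demes - 2
    elif model == "island":
        dest = rng.integers(0, n_demes - 1, idx.size)
        dest += dest >= src
    else:
        raise ConfigurationError(f"unknown migration model {model!r}")
    deme[idx] = dest
    return replace(state, deme=deme)


def reproduce(state: SimState, K: int, rng,
              config: SimulationConfig) -> SimState:
    """Replace adults by K offspring per occupied deme.

    For each offspring two parents are drawn independently with replacement
    with probability proportional to fitness W (fecundity selection; selfing
    possible), and each parent transmits one uniformly chosen allele copy per
    locus.  Demes with no adults stay empty.
    """
    n_demes = config.n_demes
    sizes = state.deme_sizes(n_demes)
    occupied = np.where(sizes > 0)[0]
    if occupied.size == 0:
        raise RuntimeError("all demes extinct")
    total = occupied.size * K
    mothers = np.empty(total, dtype=np.int64)
    fathers = np.empty(total, dtype=np.int64)
    new_deme = np.empty(total, dtype=state.deme.dtype)
    order = np.argsort(state.deme, kind="stable")
    bounds = np.searchsorted(state.deme[order], np.arange(n_demes + 1))
    out = 0
    for d in occupied:
        rows = order[bounds[d]:bounds[d + 1]]
        w = state.W[rows]
        tot_w = w.sum()
        if tot_w <= 0:  # numerically dead deme: fall back to uniform mating
            picks = rows[rng.integers(0, rows.size, 2 * K)]
        else:
            cdf = np.cumsum(w)
            cdf /= cdf[-1]
            picks = rows[np.searchsorted(cdf, rng.random(2 * K))]
        mothers[out:out + K] = picks[:K]
        fathers[out:out + K] = picks[K:]
        new_deme[out:out + K] = d
        out += K

    u = rng.random((2, total, state.dosage.shape[1]), dtype=np.float32)
    half_m = state.dosage[mothers] * np.float32(0.5)
    half_f = state.dosage[fathers] * np.float32(0.5)
    child = (u[0] < half_m).astype(np.int8)
    child += u[1] < half_f
    new = SimState(generation=state.generation + 1, deme=new_deme,
                   dosage=child, G=np.empty(total), P=np.empty(total),
                   W=np.ones(total))
    return new


def initialize(config: SimulationConfig, rng) -> SimState:
    """Secondary-contact founding state.

    The three demes at each end start at carrying capacity, fixed for the
    allele representative of their parental species (allele 0 in demes 1-3,
    allele 1 in demes 7-9); the three central demes start empty and are
    colonized through migration.  This layout requires the 9-deme geometry.
    """
    if config.n_demes != 9:
        raise ConfigurationError(
            "the secondary-contact founding layout requires n_demes == 9; "
            "construct a SimState directly for other geometries")
    K, L = config.carrying_capacity, config.n_loci
    deme = np.concatenate([np.repeat([0, 1, 2], K), np.repeat([6, 7, 8], K)])
    dosage = np.concatenate([
        np.zeros((3 * K, L), dtype=np.int8),
        np.full((3 * K, L), 2, dtype=np.int8),
    ])
    state = SimState(generation=0, deme=deme.astype(np.int16), dosage=dosage,
                     G=np.empty(6 * K), P=np.empty(6 * K), W=np.ones(6 * K))
    _assign_phenotype_fitness(state, config, rng)
    return state


# ---------------------------------------------------------------------------
# Whole-run driver
# ---------------------------------------------------------------------------

def ancestry_proxy(state: SimState) -> np.ndarray:
    """Per-individual fraction of species-1 alleles across all loci."""
    return state.dosage.mean(axis=1) / 2.0


def interspecific_het_proxy(state: SimState) -> np.ndarray:
    """Per-individual fraction of heterozygous loci (alleles are diagnostic)."""
    return (state.dosage == 1).mean(axis=1)


def parental_panel_freqs(state: SimState, n_demes: int = 9):
    """Per-locus allele-1 frequency in the two parental deme triplets.

    The end demes serve as the parental reference panels for scoring
    simulated individuals the way field data are scored (ancestry relative
    to current parental populations).  Returns (p_W, p_E).
    """
    rows_w = state.rows_in_demes([0, 1, 2])
    rows_e = state.rows_in_demes([n_demes - 3, n_demes - 2, n_demes - 1])
    p_w = state.dosage[rows_w].mean(axis=0) / 2.0
    p_e = state.dosage[rows_e].mean(axis=0) / 2.0
    return p_w, p_e


def cluster_separation(state: SimState, n_demes: int = 9) -> float:
    """Difference in mean ancestry between the two parental deme triplets.

    Near 1 while parental clusters are intact; near 0 once the zone has
    merged into a hybrid swarm.
    """
    anc = ancestry_proxy(state)
    a = anc[state.rows_in_demes([0, 1, 2])].mean()
    b = anc[state.rows_in_demes([n_demes - 3, n_demes - 2, n_demes - 1])].mean()
    return float(b - a)


def _deme_class(deme_index: np.ndarray, n_demes: int) -> np.ndarray:
    cls = np.full(deme_index.shape, "admixed", dtype=object)
    cls[deme_index < 3] = "parental_A"
    cls[deme_index >= n_demes - 3] = "parental_B"
    return cls


def _summary_rows(state: SimState, n_demes: int) -> list[dict]:
    anc = ancestry_proxy(state)
    het = interspecific_het_proxy(state)
    cls = _deme_class(state.deme, n_demes)
    rows = []
    for group in ("parental_A", "admixed", "parental_B"):
        mask = cls == group
        rows.append({
            "generation": state.generation,
            "group": group,
            "n": int(mask.sum()),
            "mean_ancestry": float(anc[mask].mean()) if mask.any() else np.nan,
            "mean_int_het": float(het[mask].mean()) if mask.any() else np.nan,
        })
    return rows


def state_to_genotype_matrix(state: SimState, n_trait_loci: int) -> GenotypeMatrix:
    """Expand dosages to allele pairs; deme index becomes the population label."""
    n, L = state.dosage.shape
    geno = np.empty((n, L, 2), dtype=np.int8)
    geno[:, :, 0] = state.dosage > 1
    geno[:, :, 1] = state.dosage > 0
    loci = [f"T{j + 1}" if j < n_trait_loci else f"N{j + 1 - n_trait_loci}"
            for j in range(L)]
    return GenotypeMatrix(
        ids=[f"g{state.generation}_i{i + 1}" for i in range(n)],
        pops=np.array([f"deme{d + 1}" for d in state.deme], dtype=object),
        loci=loci,
        geno=geno,
        marker_class=["SNP"] * L,
    )


def run(config: SimulationConfig) -> SimResult:
    """Run the simulation: reproduce -> migrate -> phenotype/fitness per
    generation, deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    state = initialize(config, rng)
    wanted = set(config.snapshot_generations)
    snapshots: list[tuple[int, GenotypeMatrix]] = []
    summary_rows: list[dict] = []

    def record(st):
        if st.generation in wanted:
            snapshots.append(
                (st.generation, state_to_genotype_matrix(st, config.n_trait_loci)))
        every = config.summary_every
        if (st.generation in wanted or st.generation == config.n_generations
                or st.generation == 0
                or (every and st.generation % every == 0)):
            summary_rows.extend(_summary_rows(st, config.n_demes))
            log.info("generation %d: deme sizes %s, mean fitness %.4f",
                     st.generation, st.deme_sizes(config.n_demes).tolist(),
                     float(st.W.mean()))

    record(state)
    for _ in range(config.n_generations):
        state = reproduce(state, config.carrying_capacity, rng, config)
        state = migrate(state, config.migration_rate, config.migration_model,
                        rng, config.n_demes)
        _assign_phenotype_fitness(state, config, rng)
        record(state)
    summary = pd.DataFrame(summary_rows)
    return SimResult(config=config, snapshots=snapshots, summary=summary,
                     final_state=state)


# ---------------------------------------------------------------------------
# Synthetic 13-population transect dataset
# ---------------------------------------------------------------------------

#: population code, latitude, longitude, elevation (m), MAT (C), MAP (mm),
#: sample size, admixture proportion (fraction of southern-species ancestry)
_FIXTURE_POPS = [
    ("FN",  58.9, 123.4,  440, 0.29,  509.0,  22, 0.00),
    ("FNL", 55.9, 124.5, 1025, 0.72,  645.0,  80, 0.12),
    ("CP",  55.1, 124.5,  930, 1.80,  622.0,  69, 0.20),
    ("BV",  54.3, 126.2,  920, 2.23,  568.0,  70, 0.28),
    ("PG",  53.6, 122.1,  900, 2.75,  769.4,  86, 0.35),
    ("MG",  54.6, 121.9,  990, 2.30, 1137.0,  81, 0.40),
    ("MR",  53.0, 119.8, 1250, 1.72, 1166.0,  50, 0.55),
    ("QL",  52.5, 120.8, 1130, 2.31,  909.0, 114, 0.50),
    ("EK",  50.0, 115.8, 1510, 1.89,  962.7,  86, 0.75),
    ("WK",  49.7, 117.1, 1430, 2.45, 1051.7,  53, 0.80),
    ("E1",  45.0, 114.8, 2195, 2.76,  994.9,  13, 1.00),
    ("E2",  42.1, 110.5, 2610, 2.51,  843.4,  35, 1.00),
    ("E3",  38.6, 111.0, 2995, 3.51,  735.7,  46, 1.00),
]


def make_fixture_dataset(seed: int, n_pops: int = 13, n_ssr: int = 10,
                         n_snp: int = 86):
    """Deterministic synthetic transect dataset for the analysis modules.

    Emulates an extensive two-species hybrid zone sampled at 13 populations
    along a ~2000 km north-south transect: multi-allelic SSR loci (5-20
    alleles, species-differentiated frequencies), bi-allelic SNP loci
    spanning diagnostic to weakly differentiated, clinal admixture
    proportions, and climate covariates (MAT, MAP, PAS, SHM) correlated with
    transect position and elevation.  The northernmost population is a pure
    northern-species (white) reference; the three southernmost are pure
    southern-species (Engelmann) references.

    Returns ``(gm_ssr, gm_snp, meta)`` where the genotype matrices share
    individuals and ``meta`` is a per-population DataFrame.
    """
    rng = np.random.default_rng(seed)
    pops = _FIXTURE_POPS[:n_pops]
    lat0 = max(p[1] for p in pops)

    meta_rows = []
    for code, lat, lon, elev, mat, mapp, n, q in pops:
        dist = (lat0 - lat) * 111.0
        meta_rows.append({
            "population": code, "latitude": lat, "longitude": lon,
            "elevation_m": elev, "distance_km": round(dist, 1),
            "MAT": mat, "MAP": mapp,
            "PAS": round(250.0 + 450.0 * q, 1),
            "SHM": round(60.0 - 30.0 * q, 1),
            "n": n,
        })
    meta = pd.DataFrame(meta_rows)

    # SSR loci: disjoint-leaning allele pools per species.
    ssr_pw, ssr_pe, ssr_codes = [], [], []
    for _ in range(n_ssr):
        k = int(rng.integers(5, 21))
        codes = 100 + 2 * np.arange(k)  # fragment-size-like codes
        conc = np.ones(k) * 0.15
        half = k // 2
        cw, ce = conc.copy(), conc.copy()
        cw[:half] += 4.0
        ce[half:] += 4.0
        ssr_pw.append(rng.dirichlet(cw))
        ssr_pe.append(rng.dirichlet(ce))
        ssr_codes.append(codes)

    # SNP loci: allele 1 is the southern-species allele; differentials span
    # diagnostic (1.0) down to weak (0.05); random orientation.
    d = np.linspace(1.0, 0.05, n_snp)
    mid = (1.0 - d) * rng.uniform(0.2, 0.8, n_snp)
    snp_pw = np.clip(mid, 0.0, 1.0)
    snp_pe = np.clip(mid + d, 0.0, 1.0)

    ids, pop_labels, h_ind = [], [], []
    for row in meta.itertuples():
        q = pops[row.Index][7]
        n = row.n
        if q in (0.0, 1.0):
            h = np.full(n, q)
        else:
            h = np.clip(rng.normal(q, 0.12, n), 0.02, 0.98)
        h_ind.append(h)
        ids.extend(f"{row.population}_{i + 1}" for i in range(n))
        pop_labels.extend([row.population] * n)
    h_ind = np.concatenate(h_ind)
    n_total = h_ind.size

    # SSR genotypes: each allele copy comes from the southern pool w.p. h.
    geno_ssr = np.empty((n_total, n_ssr, 2), dtype=np.int32)
    for j in range(n_ssr):
        k = ssr_codes[j].size
        for copy in (0, 1):
            from_e = rng.random(n_total) < h_ind
            pick_e = ssr_codes[j][rng.choice(k, n_total, p=ssr_pe[j])]
            pick_w = ssr_codes[j][rng.choice(k, n_total, p=ssr_pw[j])]
            geno_ssr[:, j, copy] = np.where(from_e, pick_e, pick_w)

    # SNP genotypes: per-copy allele-1 probability h*pE + (1-h)*pW.
    p1 = h_ind[:, None] * snp_pe[None, :] + (1 - h_ind[:, None]) * snp_pw[None, :]
    geno_snp = (rng.random((n_total, n_snp, 2)) < p1[:, :, None]).astype(np.int8)

    gm_ssr = GenotypeMatrix(ids=list(ids), pops=np.array(pop_labels, dtype=object),
                            loci=[f"SSR{j + 1:02d}" for j in range(n_ssr)],
                            geno=geno_ssr, marker_class=["SSR"] * n_ssr)
    gm_snp = GenotypeMatrix(ids=list(ids), pops=np.array(pop_labels, dtype=object),
                            loci=[f"SNP{j + 1:03d}" for j in range(n_snp)],
                            geno=geno_snp.astype(np.int32),
                            marker_class=["SNP"] * n_snp)
    return gm_ssr, gm_snp, meta
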
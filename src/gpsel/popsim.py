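"""Breeding-population simulator: the ground-truth generator.

Founder haplotypes are drawn by a first-order Markov chain along each
chromosome (allele copied from the previous locus with probability
``exp(-ld_decay * map_distance)``, else redrawn at the locus frequency),
which yields linkage disequilibrium decaying monotonically with map
distance.  Progeny are produced by meiosis with Poisson-distributed
crossovers on a Morgan map and independent assortment across chromosomes.

Two single-generation crossing designs are provided, mirroring contrasting
breeding-population structures:

* ``mixed_design`` — random non-self crosses among a panel of parents
  (default 40), giving a weakly structured population;
* ``unbalanced_design`` — five biparental full-sib families with uneven
  sizes, giving strong family structure and sampling bias.

Traits are additive (optionally with dominance at heterozygous QTL) with
environmental noise calibrated to a target narrow-sense heritability; true
additive, dominance and total genetic values are stored so prediction
accuracy can be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix


@dataclass
class GeneticMap:
    """Marker positions in Morgans; strictly increasing within chromosome."""

    chrom: np.ndarray  # (m,) int chromosome index
    pos: np.ndarray  # (m,) float position in Morgans

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, float)
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_markers(self) -> int:
        return len(self.pos)


@dataclass
class FounderSet:
    """Founder individuals: haplotype pairs on a shared map."""

    gmap: GeneticMap
    haplotypes: np.ndarray  # (n_founders, 2, m) uint8

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0]


@dataclass
class SimPopulation:
    """Simulated progeny with pedigree, true genetic values and phenotypes."""

    gmap: GeneticMap
    haplotypes: np.ndarray  # (n, 2, m)
    pedigree: np.ndarray  # (n, 2) parent indices into the founder panel
    design: str
    family: np.ndarray | None = None  # family label per individual
    a: np.ndarray | None = None  # true additive values
    d: np.ndarray | None = None  # true dominance deviations
    g: np.ndarray | None = None  # true total genetic values
    y: np.ndarray | None = None  # phenotypes
    qtl: dict | None = None
    h2_target: float | None = None
    h2_realised: float | None = None

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    def genotypes(self) -> GenotypeMatrix:
        """Dosage view: sum of the two haplotype alleles at every marker."""
        d = self.haplotypes.sum(axis=1).astype(np.int64)
        return GenotypeMatrix(
            [f"ind{i:05d}" for i in range(self.n)],
            [f"chr{c}_m{j}" for c, j in zip(self.gmap.chrom, _within_chrom_index(self.gmap))],
            d,
        )


def _within_chrom_index(gmap: GeneticMap) -> np.ndarray:
    idx = np.zeros(gmap.n_markers, dtype=int)
    for c in np.unique(gmap.chrom):
        mask = gmap.chrom == c
        idx[mask] = np.arange(mask.sum())
    return idx


def simulate_founders(
    n_founders: int = 50,
    n_chr: int = 10,
    m_per_chr: int = 100,
    chr_length: float = 1.0,
    ld_decay: float = 20.0,
    freq_range: tuple[float, float] = (0.1, 0.9),
    seed: int = 0,
) -> FounderSet:
    """Markov-chain founder haplotypes with distance-decaying LD.

    ``ld_decay`` is the exponential rate per Morgan: the copy probability
    between adjacent loci at map distance d is exp(-ld_decay * d), so
    ld_decay -> 0 gives near-perfect LD and large values independence.
    """
    if min(n_founders, n_chr, m_per_chr) < 1 or chr_length <= 0:
        raise ValueError("all simulator counts must be positive")
    rng = np.random.default_rng(seed)
    m = n_chr * m_per_chr
    chrom = np.repeat(np.arange(n_chr), m_per_chr)
    pos = np.tile(np.linspace(0, chr_length, m_per_chr + 1)[1:], n_chr)
    freqs = rng.uniform(*freq_range, size=m)
    n_hap = 2 * n_founders
    haps = np.zeros((n_hap, m), dtype=np.uint8)
    for c in range(n_chr):
        cols = np.flatnonzero(chrom == c)
        haps[:, cols[0]] = rng.random(n_hap) < freqs[cols[0]]
        for prev, cur in zip(cols[:-1], cols[1:]):
            dist = pos[cur] - pos[prev]
            rho = np.exp(-ld_decay * dist)
            copy = rng.random(n_hap) < rho
            fresh = (rng.random(n_hap) < freqs[cur]).astype(np.uint8)
            haps[:, cur] = np.where(copy, haps[:, prev], fresh)
    gmap = GeneticMap(chrom, pos)
    return FounderSet(gmap, haps.reshape(n_founders, 2, m))


def meiosis(parent_haps: np.ndarray, gmap: GeneticMap, rng: np.random.Generator) -> np.ndarray:
    """One gamete: Poisson(L) crossovers per chromosome at uniform map
    positions, strands alternating at each crossover, chromosomes assorting
    independently."""
    m = gmap.n_markers
    gamete = np.empty(m, dtype=np.uint8)
    for c in np.unique(gmap.chrom):
        cols = gmap.chrom == c
        p = gmap.pos[cols]
        length = p[-1] - p[0]
        n_cx = rng.poisson(length)
        strand = np.full(cols.sum(), rng.integers(2), dtype=np.int64)
        if n_cx > 0:
            cx = np.sort(rng.uniform(p[0], p[-1], size=n_cx))
            for x in cx:
                strand[p > x] ^= 1
        gamete[cols] = parent_haps[strand, np.flatnonzero(cols)]
    return gamete


def mixed_design(
    founders: FounderSet, n_parents: int = 40, n_progeny: int = 500, seed: int = 0
) -> SimPopulation:
    """Random non-self crosses among the first ``n_parents`` founders."""
    if n_parents < 2:
        raise ValueError("need at least two parents")
    if founders.n_founders < n_parents:
        raise ValueError(f"only {founders.n_founders} founders for {n_parents} parents")
    rng = np.random.default_rng(seed)
    m = founders.gmap.n_markers
    haps = np.empty((n_progeny, 2, m), dtype=np.uint8)
    ped = np.empty((n_progeny, 2), dtype=int)
    for i in range(n_progeny):
        p1, p2 = rng.choice(n_parents, size=2, replace=False)
        haps[i, 0] = meiosis(founders.haplotypes[p1], founders.gmap, rng)
        haps[i, 1] = meiosis(founders.haplotypes[p2], founders.gmap, rng)
        ped[i] = (min(p1, p2), max(p1, p2))
    return SimPopulation(founders.gmap, haps, ped, "mixed")


def unbalanced_design(
    founders: FounderSet,
    family_sizes: list[int] = (200, 100, 50, 25, 10),
    seed: int = 0,
) -> SimPopulation:
    """Five biparental full-sib families of uneven size."""
    family_sizes = list(family_sizes)
    n_fam = len(family_sizes)
    if founders.n_founders < 2 * n_fam:
        raise ValueError(f"need >= {2 * n_fam} founders for {n_fam} distinct parent pairs")
    rng = np.random.default_rng(seed)
    parents = rng.choice(founders.n_founders, size=2 * n_fam, replace=False).reshape(n_fam, 2)
    m = founders.gmap.n_markers
    n = sum(family_sizes)
    haps = np.empty((n, 2, m), dtype=np.uint8)
    ped = np.empty((n, 2), dtype=int)
    fam = np.empty(n, dtype=int)
    i = 0
    for f, size in enumerate(family_sizes):
        p1, p2 = parents[f]
        for _ in range(size):
            haps[i, 0] = meiosis(founders.haplotypes[p1], founders.gmap, rng)
            haps[i, 1] = meiosis(founders.haplotypes[p2], founders.gmap, rng)
            ped[i] = (p1, p2)
            fam[i] = f
            i += 1
    return SimPopulation(founders.gmap, haps, ped, "unbalanced", family=fam)


def simulate_trait(
    pop: SimPopulation,
    n_qtl: int = 100,
    h2: float = 0.5,
    dominance_degree: float = 0.0,
    seed: int = 0,
) -> SimPopulation:
    """Attach an additive(+dominance) trait at target heritability.

    QTL are sampled without replacement among segregating markers; additive
    effects are N(0, 1); each QTL's dominance deviation (applied to
    heterozygotes) is ``dominance_degree * |additive effect|``.  Noise
    variance is set from the realised genetic variance so
    var(g)/var(y) ~= h2; h2 = 1 gives y = g exactly.
    """
    if not 0 < h2 <= 1:
        raise ValueError("h2 must be in (0, 1]")
    rng = np.random.default_rng(seed)
    dos = pop.haplotypes.sum(axis=1)
    seg = np.flatnonzero(np.ptp(dos, axis=0) > 0)
    if len(seg) == 0:
        raise ValueError("no segregating markers: genetic variance would be zero")
    if n_qtl > len(seg):
        raise ValueError(f"n_qtl={n_qtl} exceeds {len(seg)} segregating markers")
    qtl = np.sort(rng.choice(seg, size=n_qtl, replace=False))
    alpha = rng.standard_normal(n_qtl)
    a = dos[:, qtl].astype(float) @ alpha
    het = dos[:, qtl] == 1
    d = het @ (dominance_degree * np.abs(alpha))
    g = a + d
    var_g = g.var()
    if var_g <= 0:
        raise ValueError("zero genetic variance at sampled QTL")
    if h2 == 1.0:
        e = np.zeros(pop.n)
    else:
        e = rng.standard_normal(pop.n) * np.sqrt(var_g * (1 - h2) / h2)
    y = g + e
    pop.a, pop.d, pop.g, pop.y = a, d, g, y
    pop.qtl = {"index": qtl, "additive_effect": alpha,
               "dominance_effect": dominance_degree * np.abs(alpha)}
    pop.h2_target = h2
    pop.h2_realised = float(var_g / y.var())
    return pop


def benchmark_datasets(
    seed: int = 0,
    n_mixed: int = 500,
    family_sizes: list[int] = (200, 100, 50, 25, 10),
    n_qtl: int = 100,
    h2: float = 0.5,
    dominance_degree: float = 0.0,
    n_chr: int = 10,
    m_per_chr: int = 100,
) -> dict[str, SimPopulation]:
    """Both benchmark designs with traits, as a pure function of seed."""
    founders = simulate_founders(n_founders=50, n_chr=n_chr, m_per_chr=m_per_chr, seed=seed)
    mixed = simulate_trait(
        mixed_design(founders, 40, n_mixed, seed=seed + 1),
        n_qtl=n_qtl, h2=h2, dominance_degree=dominance_degree, seed=seed + 2,
    )
    unbal = simulate_trait(
        unbalanced_design(founders, family_sizes, seed=seed + 3),
        n_qtl=n_qtl, h2=h2, dominance_degree=dominance_degree, seed=seed + 4,
    )
    return {"mixed": mixed, "unbalanced": unbal}
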
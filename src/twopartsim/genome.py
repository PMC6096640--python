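"""Founder genomes, meiosis, crossing, doubled haploids and additive traits.

The simulation substrate is a diploid, biallelic genome.  Haplotypes are
stored as dense ``uint8`` arrays of shape ``(n_individuals, 2, n_loci)``
with alleles coded 0/1; dosages are the phase sums (0/1/2).  Recombination
follows the Haldane model: the number of crossovers on a chromosome is
Poisson with mean equal to the chromosome length in Morgans and chiasma
positions are uniform, with no interference.

Loci are partitioned (not necessarily exclusively) into causal loci, which
carry allele substitution effects, and marker loci, which are observed by
the genotyping platform and feed genomic prediction and marker-based
coancestry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "HaplotypePopulation",
    "TraitArchitecture",
    "simulate_founders",
    "make_cross",
    "make_crosses",
    "make_dh",
    "genetic_values",
    "genic_variance",
]


class InvalidConfigurationError(ValueError):
    """Raised when a genome or simulation configuration is unusable."""


@dataclass(frozen=True)
class GeneticMap:
    """Genetic map: chromosome assignment and position (Morgans) per locus.

    Parameters
    ----------
    chromosome
        Chromosome index (0-based) per locus, non-decreasing.
    position
        Genetic position in Morgans, strictly increasing within a
        chromosome.
    is_causal, is_marker
        Role flags per locus.  A locus may be causal, marker, both, or
        neither.
    chrom_length
        Length in Morgans of each chromosome (expected number of
        crossovers per meiosis).
    """

    chromosome: np.ndarray
    position: np.ndarray
    is_causal: np.ndarray
    is_marker: np.ndarray
    chrom_length: np.ndarray

    def __post_init__(self):
        chrom = np.asarray(self.chromosome, dtype=np.int64)
        pos = np.asarray(self.position, dtype=np.float64)
        causal = np.asarray(self.is_causal, dtype=bool)
        marker = np.asarray(self.is_marker, dtype=bool)
        length = np.asarray(self.chrom_length, dtype=np.float64)
        if chrom.size == 0:
            raise InvalidConfigurationError("map must contain at least one locus")
        if not (len(chrom) == len(pos) == len(causal) == len(marker)):
            raise InvalidConfigurationError("map arrays must have equal length")
        if np.any(np.diff(chrom) < 0):
            raise InvalidConfigurationError("chromosome indices must be sorted")
        if length.size != chrom.max() + 1 or np.any(length <= 0):
            raise InvalidConfigurationError("need a positive length per chromosome")
        for c in range(length.size):
            p = pos[chrom == c]
            if p.size == 0:
                raise InvalidConfigurationError(f"chromosome {c} has no loci")
            if np.any(np.diff(p) <= 0):
                raise InvalidConfigurationError(
                    f"positions must be strictly increasing on chromosome {c}"
                )
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "is_causal", causal)
        object.__setattr__(self, "is_marker", marker)
        object.__setattr__(self, "chrom_length", length)

    @property
    def n_loci(self) -> int:
        return self.position.size

    @property
    def n_chromosomes(self) -> int:
        return self.chrom_length.size

    @property
    def causal_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_causal)

    @property
    def marker_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_marker)

    @classmethod
    def regular(
        cls,
        n_chromosomes: int = 10,
        n_causal_per_chrom: int = 100,
        n_markers_per_chrom: int = 100,
        length_morgan: float = 1.0,
    ) -> "GeneticMap":
        """Evenly spaced map with causal and marker loci interleaved.

        Loci alternate causal/marker along each chromosome so the two
        classes cover the same genetic territory.
        """
        if n_chromosomes <= 0 or (n_causal_per_chrom + n_markers_per_chrom) <= 0:
            raise InvalidConfigurationError("counts must be positive")
        per = n_causal_per_chrom + n_markers_per_chrom
        chrom = np.repeat(np.arange(n_chromosomes), per)
        pos_one = (np.arange(per) + 0.5) / per * length_morgan
        pos = np.tile(pos_one, n_chromosomes)
        # interleave: even slots causal until exhausted, odd slots markers
        causal_one = np.zeros(per, dtype=bool)
        marker_one = np.zeros(per, dtype=bool)
        ratio = n_causal_per_chrom / per if per else 0.0
        acc = 0.0
        nc = nm = 0
        for i in range(per):
            acc += ratio
            if (acc >= nc + 1 and nc < n_causal_per_chrom) or nm >= n_markers_per_chrom:
                causal_one[i] = True
                nc += 1
            else:
                marker_one[i] = True
                nm += 1
        causal = np.tile(causal_one, n_chromosomes)
        marker = np.tile(marker_one, n_chromosomes)
        return cls(chrom, pos, causal, marker, np.full(n_chromosomes, length_morgan))


@dataclass
class HaplotypePopulation:
    """A set of diploid individuals with phased haplotypes.

    ``haplotypes`` has shape ``(n, 2, n_loci)`` with alleles in {0, 1}.
    ``pool`` optionally labels each individual ``"F"``/``"M"``; ``cohort``
    tags the population with a year/stage label.
    """

    ids: np.ndarray
    haplotypes: np.ndarray
    gmap: GeneticMap
    pool: np.ndarray | None = None
    cohort: str = ""

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise InvalidConfigurationError("haplotypes must be (n, 2, loci)")
        if self.haplotypes.shape[2] != self.gmap.n_loci:
            raise InvalidConfigurationError("haplotype width must match the map")
        if self.haplotypes.shape[0] != self.ids.size:
            raise InvalidConfigurationError("one id per individual required")
        if len(set(self.ids.tolist())) != self.ids.size:
            raise InvalidConfigurationError("individual ids must be unique")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise InvalidConfigurationError("alleles must be 0/1")

    @property
    def n(self) -> int:
        return self.ids.size

    def dosages(self, loci: np.ndarray | None = None) -> np.ndarray:
        """Allele dosages (0/1/2), optionally restricted to given loci."""
        d = self.haplotypes.sum(axis=1, dtype=np.int16)
        return d if loci is None else d[:, loci]

    def marker_dosages(self) -> np.ndarray:
        return self.dosages(self.gmap.marker_indices)

    def allele_frequencies(self, loci: np.ndarray | None = None) -> np.ndarray:
        if self.n == 0:
            raise InvalidConfigurationError("empty population")
        return self.dosages(loci).mean(axis=0) / 2.0

    def heterozygosity(self) -> np.ndarray:
        """Fraction of heterozygous loci per individual."""
        return (self.haplotypes[:, 0, :] != self.haplotypes[:, 1, :]).mean(axis=1)

    def index_of(self, ids) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.ids.tolist())}
        try:
            return np.array([lookup[v] for v in np.atleast_1d(ids)], dtype=np.int64)
        except KeyError as e:  # pragma: no cover - message only
            raise KeyError(f"unknown individual id {e.args[0]!r}") from None

    def subset(self, idx, cohort: str | None = None) -> "HaplotypePopulation":
        idx = np.asarray(idx)
        pool = None if self.pool is None else self.pool[idx]
        return HaplotypePopulation(
            self.ids[idx], self.haplotypes[idx], self.gmap, pool,
            self.cohort if cohort is None else cohort,
        )

    @staticmethod
    def concatenate(pops: list["HaplotypePopulation"], cohort: str = "") -> "HaplotypePopulation":
        pops = [p for p in pops if p is not None and p.n > 0]
        if not pops:
            raise InvalidConfigurationError("nothing to concatenate")
        gmap = pops[0].gmap
        ids = np.concatenate([p.ids for p in pops])
        haps = np.concatenate([p.haplotypes for p in pops], axis=0)
        return HaplotypePopulation(ids, haps, gmap, None, cohort)

    def to_dosage_csv(self, path) -> None:
        """Write marker dosages as CSV: one row per individual, header of
        locus ids, first column the individual id."""
        midx = self.gmap.marker_indices
        cols = [f"m{j}" for j in midx]
        df = pd.DataFrame(self.marker_dosages(), columns=cols)
        df.insert(0, "id", self.ids)
        df.to_csv(path, index=False)

    def to_haplotype_csv(self, path) -> None:
        """Serialise phased haplotypes as CSV.

        Layout: two rows per individual (columns ``id``, ``phase`` in
        {0, 1}, then one 0/1 allele column ``L<j>`` per locus in map
        order).  Round-trips through :meth:`from_haplotype_csv` against
        the same map.
        """
        n, _, L = self.haplotypes.shape
        flat = self.haplotypes.reshape(2 * n, L)
        df = pd.DataFrame(flat, columns=[f"L{j}" for j in range(L)])
        df.insert(0, "phase", np.tile([0, 1], n))
        df.insert(0, "id", np.repeat(self.ids, 2))
        df.to_csv(path, index=False)

    @classmethod
    def from_haplotype_csv(cls, path, gmap: GeneticMap,
                           cohort: str = "") -> "HaplotypePopulation":
        df = pd.read_csv(path)
        ids = df["id"].to_numpy()[::2]
        alleles = df[[f"L{j}" for j in range(gmap.n_loci)]].to_numpy(
            dtype=np.uint8
        )
        haps = alleles.reshape(ids.size, 2, gmap.n_loci)
        return cls(ids.astype(str), haps, gmap, None, cohort)


@dataclass(frozen=True)
class TraitArchitecture:
    """Additive trait: allele substitution effects at causal loci."""

    causal_indices: np.ndarray
    alpha: np.ndarray
    intercept: float = 0.0

    def __post_init__(self):
        ci = np.asarray(self.causal_indices, dtype=np.int64)
        a = np.asarray(self.alpha, dtype=np.float64)
        if ci.size != a.size:
            raise InvalidConfigurationError("one effect per causal locus required")
        if not np.all(np.isfinite(a)):
            raise InvalidConfigurationError("effects must be finite")
        object.__setattr__(self, "causal_indices", ci)
        object.__setattr__(self, "alpha", a)

    @classmethod
    def sample(
        cls,
        gmap: GeneticMap,
        founders: HaplotypePopulation,
        rng: np.random.Generator,
        target_genic_variance: float = 1.0,
        intercept: float = 0.0,
    ) -> "TraitArchitecture":
        """Draw effects N(0, 1) and rescale so the founder genic variance
        equals ``target_genic_variance``."""
        ci = gmap.causal_indices
        if ci.size == 0:
            raise InvalidConfigurationError("map defines no causal loci")
        alpha = rng.standard_normal(ci.size)
        p = founders.allele_frequencies(ci)
        v = genic_variance(p, alpha)
        if v <= 0:
            raise InvalidConfigurationError("founders are fixed at all causal loci")
        alpha *= np.sqrt(target_genic_variance / v)
        return cls(ci, alpha, intercept)


# ---------------------------------------------------------------------------
# meiosis


def _gametes(
    pop: HaplotypePopulation, parent_idx: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample one recombinant gamete per entry of ``parent_idx``.

    Vectorised over gametes: per chromosome, crossover counts are
    Poisson(length) and positions uniform on (0, length); the transmitted
    phase at a locus is the starting phase flipped once per crossover to
    the left of the locus.
    """
    parent_idx = np.asarray(parent_idx, dtype=np.int64)
    g = parent_idx.size
    gmap = pop.gmap
    out = np.empty((g, gmap.n_loci), dtype=np.uint8)
    haps = pop.haplotypes
    for c in range(gmap.n_chromosomes):
        sl = gmap.chromosome == c
        pos = gmap.position[sl]
        length = gmap.chrom_length[c]
        k = rng.poisson(length, size=g)
        kmax = int(k.max()) if g else 0
        start = rng.integers(0, 2, size=g, dtype=np.uint8)
        if kmax == 0:
            phase = np.broadcast_to(start[:, None], (g, pos.size))
        else:
            xo = rng.uniform(0.0, length, size=(g, kmax))
            xo[np.arange(kmax)[None, :] >= k[:, None]] = np.inf
            flips = (xo[:, :, None] < pos[None, None, :]).sum(axis=1)
            phase = (start[:, None] + flips) % 2
        h = haps[parent_idx][:, :, sl]
        out[:, sl] = np.where(phase == 0, h[:, 0, :], h[:, 1, :])
    return out


def make_cross(
    pop: HaplotypePopulation,
    mother,
    father,
    n_progeny: int,
    rng: np.random.Generator,
    id_prefix: str = "x",
) -> HaplotypePopulation:
    """Cross two individuals; each progeny gets one recombinant gamete per
    parent.  Selfing is rejected."""
    if mother == father:
        raise InvalidConfigurationError("selfing is not allowed in crossing plans")
    return make_crosses(pop, [(mother, father)], [n_progeny], rng, id_prefix)


def make_crosses(
    pop: HaplotypePopulation,
    pairs: list[tuple],
    n_progeny: list[int] | int,
    rng: np.random.Generator,
    id_prefix: str = "x",
    cohort: str = "",
) -> HaplotypePopulation:
    """Execute a crossing plan in one vectorised batch.

    ``pairs`` is a list of (mother_id, father_id); ``n_progeny`` a count per
    cross (or a single shared count).  Progeny ids are
    ``{prefix}{cross}.{j}``.
    """
    if np.isscalar(n_progeny):
        n_progeny = [int(n_progeny)] * len(pairs)
    if len(n_progeny) != len(pairs):
        raise InvalidConfigurationError("one progeny count per cross required")
    for m, f in pairs:
        if m == f:
            raise InvalidConfigurationError("selfing is not allowed in crossing plans")
    mothers = pop.index_of([m for m, _ in pairs])
    fathers = pop.index_of([f for _, f in pairs])
    counts = np.asarray(n_progeny, dtype=np.int64)
    mat_idx = np.repeat(mothers, counts)
    pat_idx = np.repeat(fathers, counts)
    mg = _gametes(pop, mat_idx, rng)
    pg = _gametes(pop, pat_idx, rng)
    haps = np.stack([mg, pg], axis=1)
    ids = np.array(
        [f"{id_prefix}{i}.{j}" for i, n in enumerate(counts) for j in range(n)]
    )
    return HaplotypePopulation(ids, haps, pop.gmap, None, cohort)


def make_dh(
    pop: HaplotypePopulation,
    parent,
    n_dh: int,
    rng: np.random.Generator,
    id_prefix: str = "dh",
) -> HaplotypePopulation:
    """Doubled-haploid lines: one recombinant gamete per line, doubled."""
    return make_dh_lines(pop, [parent], [n_dh], rng, id_prefix)


def make_dh_lines(
    pop: HaplotypePopulation,
    parents: list,
    n_dh: list[int] | int,
    rng: np.random.Generator,
    id_prefix: str = "dh",
    cohort: str = "",
) -> HaplotypePopulation:
    if np.isscalar(n_dh):
        n_dh = [int(n_dh)] * len(parents)
    idx = pop.index_of(parents)
    counts = np.asarray(n_dh, dtype=np.int64)
    rep = np.repeat(idx, counts)
    gam = _gametes(pop, rep, rng)
    haps = np.stack([gam, gam], axis=1)
    ids = np.array(
        [f"{id_prefix}{i}.{j}" for i, n in enumerate(counts) for j in range(n)]
    )
    return HaplotypePopulation(ids, haps, pop.gmap, None, cohort)


# ---------------------------------------------------------------------------
# founders


def simulate_founders(
    n_individuals: int,
    gmap: GeneticMap,
    rng_seed: int,
    maf_floor: float = 0.05,
    mating_generations: int = 10,
) -> HaplotypePopulation:
    """Simulate a polymorphic founder population.

    Per-locus allele frequencies are drawn from U(``maf_floor``,
    1 − ``maf_floor``) and haplotypes as independent Bernoulli draws, then
    the population undergoes ``mating_generations`` rounds of random mating
    (constant size, no selfing) to build linkage disequilibrium.  Loci
    whose realised minor allele frequency drops below ``maf_floor`` are
    re-drawn until every locus segregates.
    """
    if n_individuals < 2:
        raise InvalidConfigurationError("need at least two founders")
    if gmap.n_loci == 0:
        raise InvalidConfigurationError("map has no loci")
    rng = np.random.default_rng(rng_seed)
    L = gmap.n_loci
    p = rng.uniform(maf_floor, 1.0 - maf_floor, size=L)
    haps = (rng.random((n_individuals, 2, L)) < p).astype(np.uint8)
    pop = HaplotypePopulation(
        np.array([f"f{i}" for i in range(n_individuals)]), haps, gmap, None, "founder"
    )
    for _ in range(mating_generations):
        mothers = rng.integers(0, n_individuals, size=n_individuals)
        shift = rng.integers(1, n_individuals, size=n_individuals)
        fathers = (mothers + shift) % n_individuals  # never the mother
        mg = _gametes(pop, mothers, rng)
        pg = _gametes(pop, fathers, rng)
        pop = HaplotypePopulation(pop.ids, np.stack([mg, pg], axis=1), gmap, None, "founder")
    # enforce segregation: re-draw columns that drifted past the floor
    for _ in range(100):
        freq = pop.allele_frequencies()
        maf = np.minimum(freq, 1.0 - freq)
        bad = np.flatnonzero(maf < maf_floor)
        if bad.size == 0:
            break
        pb = rng.uniform(0.2, 0.8, size=bad.size)
        redraw = (rng.random((n_individuals, 2, bad.size)) < pb).astype(np.uint8)
        pop.haplotypes[:, :, bad] = redraw
    else:  # pragma: no cover - vanishing probability
        raise InvalidConfigurationError("could not achieve the MAF floor")
    return pop


# ---------------------------------------------------------------------------
# trait values


def genetic_values(pop: HaplotypePopulation, trait: TraitArchitecture) -> np.ndarray:
    """True genetic value per individual: intercept + Σ dosage_i · α_i."""
    d = pop.dosages(trait.causal_indices)
    return trait.intercept + d.astype(np.float64) @ trait.alpha


def genic_variance(freqs: np.ndarray, alpha: np.ndarray) -> float:
    """Genic variance 2 Σ p_i (1 − p_i) α_i² at the causal loci.

    This is the additive variance attributable to allele frequencies alone,
    ignoring linkage disequilibrium and inbreeding, which makes it
    comparable between inbred and outbred cohorts.
    """
    p = np.asarray(freqs, dtype=np.float64)
    a = np.asarray(alpha, dtype=np.float64)
    if p.shape != a.shape:
        raise InvalidConfigurationError("frequency and effect vectors differ in length")
    if np.any((p < 0) | (p > 1)):
        raise InvalidConfigurationError("frequencies must lie in [0, 1]")
    return float(2.0 * np.sum(p * (1.0 - p) * a * a))
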
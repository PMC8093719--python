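"""Synthetic spatial populations with known truth.

Generates multi-generation polygamous populations with spatially clustered
families, sex-specific natal dispersal, multilocus microsatellite genotypes
drawn from explicit allele frequencies, and a field-sampling layer that
applies partial sampling, replicate amplification, allelic dropout and
false-allele error.  The true pedigree, genotypes and coordinates are
retained so every downstream stage (consolidation, parentage, network,
spatial cohesion) can be validated against ground truth.

Demography is deliberately simple: discrete non-overlapping generations,
Poisson litter sizes per female, sires drawn uniformly (with replacement
under polygamy) from the males of the parental generation, and isotropic
Gaussian settlement of offspring around the dam.  Each spatial cluster
carries a philopatry level in [0, 1] that shrinks the dispersal scale of
offspring born there, producing the contrast between spatially cohesive
family areas and dispersing areas.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "AreaCluster",
    "SimulationConfig",
    "FrequencyTable",
    "TrueIndividual",
    "TruePopulation",
    "GenotypeObservation",
    "draw_allele_frequencies",
    "simulate_population",
    "apply_sampling_and_error",
    "write_genotype_csv",
    "write_pedigree_csv",
]


# ---------------------------------------------------------------------------
# configuration and domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AreaCluster:
    """A labelled spatial cluster of the founding population.

    ``philopatry`` in [0, 1] scales down the natal dispersal of offspring
    whose dam belongs to this cluster: the effective dispersal scale is
    ``dispersal_scale * (1 - philopatry)``.  1 means offspring settle on
    top of the dam; 0 means full dispersal.
    """

    label: str
    center: tuple[float, float]
    spread: float = 5.0
    philopatry: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.philopatry <= 1.0:
            raise ValueError(f"philopatry must be in [0, 1], got {self.philopatry}")
        if self.spread < 0:
            raise ValueError("cluster spread must be non-negative")


def _default_layout() -> tuple[AreaCluster, ...]:
    # Two philopatric ("family") clusters and two dispersing clusters on a
    # 100 x 100 map, mirroring the contrast between cohesive and dispersed
    # local areas.
    return (
        AreaCluster("north_a", (20.0, 80.0), 6.0, philopatry=0.9),
        AreaCluster("north_b", (80.0, 80.0), 6.0, philopatry=0.9),
        AreaCluster("south_a", (20.0, 20.0), 6.0, philopatry=0.1),
        AreaCluster("south_b", (80.0, 20.0), 6.0, philopatry=0.1),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic population and of the sampling layer.

    Distances are planar map units; rates are per-allele probabilities.
    A fixed ``seed`` makes every product of the simulation byte-identical.
    """

    n_founders: int = 120
    n_generations: int = 4
    mean_offspring_per_female: float = 2.0
    polygamy: bool = True
    n_loci: int = 15
    alleles_per_locus: int = 8
    dispersal_scale_female: float = 30.0
    dispersal_scale_male: float = 50.0
    area_layout: tuple[AreaCluster, ...] = field(default_factory=_default_layout)
    sampling_fraction: float = 0.20
    dropout_rate: float = 0.0077
    false_allele_rate: float = 0.00032
    locus_failure_rate: float = 0.02
    replicate_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sampling_fraction", "dropout_rate", "false_allele_rate",
                     "locus_failure_rate", "replicate_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_founders", "n_generations", "n_loci", "alleles_per_locus"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mean_offspring_per_female < 0:
            raise ValueError("mean_offspring_per_female must be >= 0")
        if not isinstance(self.area_layout, tuple):
            object.__setattr__(self, "area_layout", tuple(self.area_layout))
        if not self.area_layout:
            raise ValueError("area_layout needs at least one cluster")


@dataclass(frozen=True)
class FrequencyTable:
    """Per-locus allele frequencies; the base measure for genotype draws
    and for Hardy-Weinberg marginals in parentage likelihoods."""

    freqs: tuple[tuple[str, tuple[tuple[int, float], ...]], ...]

    @classmethod
    def from_dict(cls, d: Mapping[str, Mapping[int, float]]) -> "FrequencyTable":
        rows = []
        for locus in d:
            entries = tuple(sorted(d[locus].items()))
            total = sum(f for _, f in entries)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {locus} sum to {total}, not 1")
            if any(f <= 0 for _, f in entries):
                raise ValueError(f"non-positive frequency at {locus}")
            rows.append((locus, entries))
        return cls(tuple(rows))

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(locus for locus, _ in self.freqs)

    def alleles(self, locus: str) -> tuple[int, ...]:
        return tuple(a for a, _ in dict(self.freqs)[locus])

    def frequency(self, locus: str, allele: int) -> float:
        return dict(dict(self.freqs)[locus]).get(allele, 0.0)

    def as_dict(self) -> dict[str, dict[int, float]]:
        return {locus: dict(entries) for locus, entries in self.freqs}

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["locus", "allele", "frequency"])
            for locus, entries in self.freqs:
                for allele, f in entries:
                    w.writerow([locus, allele, repr(f)])

    @classmethod
    def read_csv(cls, path) -> "FrequencyTable":
        table: dict[str, dict[int, float]] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                table.setdefault(row["locus"], {})[int(row["allele"])] = float(row["frequency"])
        return cls.from_dict(table)


@dataclass
class TrueIndividual:
    individual_id: str
    sex: str                       # 'F' or 'M'
    generation: int
    genotype: dict[str, tuple[int, int]]
    x: float
    y: float
    natal_area: str


@dataclass
class TruePopulation:
    """Ground truth: individuals with genotypes/sex/coordinates and the
    true pedigree (offspring id -> (dam id, sire id))."""

    individuals: dict[str, TrueIndividual]
    pedigree: dict[str, tuple[str, str]]
    empty_generations: list[int] = field(default_factory=list)

    def founders(self) -> list[str]:
        return [i for i in self.individuals if i not in self.pedigree]

    def offspring_counts(self) -> dict[str, int]:
        counts = {i: 0 for i in self.individuals}
        for dam, sire in self.pedigree.values():
            counts[dam] += 1
            counts[sire] += 1
        return counts


@dataclass
class GenotypeObservation:
    """One field/lab sample: a (possibly erroneous, possibly partial)
    read of an individual's multilocus genotype."""

    sample_id: str
    true_individual_id: str
    stratum: str
    year: int
    source: str
    sex: str
    x: float
    y: float
    genotype: dict[str, tuple[int, int]]   # unordered pair stored sorted


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def locus_name(i: int) -> str:
    return f"L{i + 1:02d}"


def draw_allele_frequencies(n_loci: int, alleles_per_locus: int, seed: int,
                            concentration: float = 1.0) -> FrequencyTable:
    """Draw per-locus allele frequencies from a symmetric Dirichlet.

    The symmetric prior keeps loci exchangeable; ``concentration`` = 1 gives
    uniform draws over the simplex, larger values give more even spectra.
    Deterministic for a fixed seed.
    """
    if n_loci < 1 or alleles_per_locus < 1:
        raise ValueError("n_loci and alleles_per_locus must be >= 1")
    rng = np.random.default_rng(seed)
    table: dict[str, dict[int, float]] = {}
    for i in range(n_loci):
        raw = rng.dirichlet(np.full(alleles_per_locus, concentration))
        # clip away zeros from underflow, renormalise exactly
        raw = np.clip(raw, 1e-6, None)
        raw = raw / raw.sum()
        table[locus_name(i)] = {a + 1: float(f) for a, f in enumerate(raw)}
    return FrequencyTable.from_dict(table)


# ---------------------------------------------------------------------------
# demography
# ---------------------------------------------------------------------------

def _draw_genotype(rng: np.random.Generator, freqs: FrequencyTable) -> dict[str, tuple[int, int]]:
    g = {}
    for locus, entries in freqs.freqs:
        alleles = np.array([a for a, _ in entries])
        p = np.array([f for _, f in entries])
        pair = rng.choice(alleles, size=2, p=p)
        g[locus] = (int(min(pair)), int(max(pair)))
    return g


def _mendelian_child(rng: np.random.Generator,
                     dam: dict[str, tuple[int, int]],
                     sire: dict[str, tuple[int, int]]) -> dict[str, tuple[int, int]]:
    g = {}
    for locus in dam:
        a = dam[locus][rng.integers(2)]
        b = sire[locus][rng.integers(2)]
        g[locus] = (min(a, b), max(a, b))
    return g


def simulate_population(config: SimulationConfig,
                        freqs: FrequencyTable | None = None) -> TruePopulation:
    """Simulate a multi-generation population with a known pedigree.

    Founders (generation 0) are placed in the configured spatial clusters
    with Hardy-Weinberg genotypes.  Each later generation is produced by
    the females of the previous one: litter size is Poisson distributed,
    each offspring receives one allele per locus from each parent, and
    settles at the dam's location plus an isotropic Gaussian displacement
    whose scale is sex-specific and shrunk by the natal cluster's
    philopatry.  Under polygamy every offspring draws its sire
    independently; otherwise each female keeps a single mate.

    A generation with no individuals, or no males, ends reproduction and is
    recorded in ``empty_generations`` rather than raising.
    """
    rng = np.random.default_rng(config.seed)
    if freqs is None:
        freqs = draw_allele_frequencies(config.n_loci, config.alleles_per_locus,
                                        seed=int(rng.integers(2**31)))
    clusters = {c.label: c for c in config.area_layout}

    individuals: dict[str, TrueIndividual] = {}
    pedigree: dict[str, tuple[str, str]] = {}
    empty: list[int] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"T{counter:05d}"

    # founders
    current: list[str] = []
    labels = list(clusters)
    for k in range(config.n_founders):
        cluster = clusters[labels[k % len(labels)]]
        iid = new_id()
        dx, dy = rng.normal(0.0, cluster.spread, size=2)
        individuals[iid] = TrueIndividual(
            individual_id=iid,
            sex="F" if rng.random() < 0.5 else "M",
            generation=0,
            genotype=_draw_genotype(rng, freqs),
            x=float(cluster.center[0] + dx),
            y=float(cluster.center[1] + dy),
            natal_area=cluster.label,
        )
        current.append(iid)

    for gen in range(1, config.n_generations):
        females = [i for i in current if individuals[i].sex == "F"]
        males = [i for i in current if individuals[i].sex == "M"]
        if not females or not males:
            empty.append(gen)
            current = []
            continue
        nxt: list[str] = []
        for dam_id in females:
            dam = individuals[dam_id]
            n_off = int(rng.poisson(config.mean_offspring_per_female))
            if n_off == 0:
                continue
            if config.polygamy:
                sire_ids = [males[int(rng.integers(len(males)))] for _ in range(n_off)]
            else:
                mate = males[int(rng.integers(len(males)))]
                sire_ids = [mate] * n_off
            cluster = clusters[dam.natal_area]
            for sire_id in sire_ids:
                sire = individuals[sire_id]
                iid = new_id()
                sex = "F" if rng.random() < 0.5 else "M"
                scale = (config.dispersal_scale_female if sex == "F"
                         else config.dispersal_scale_male)
                scale *= (1.0 - cluster.philopatry)
                dx, dy = rng.normal(0.0, max(scale, 1e-9), size=2)
                individuals[iid] = TrueIndividual(
                    individual_id=iid,
                    sex=sex,
                    generation=gen,
                    genotype=_mendelian_child(rng, dam.genotype, sire.genotype),
                    x=float(dam.x + dx),
                    y=float(dam.y + dy),
                    natal_area=dam.natal_area,
                )
                pedigree[iid] = (dam_id, sire_id)
                nxt.append(iid)
        if not nxt:
            empty.append(gen)
        current = nxt

    return TruePopulation(individuals=individuals, pedigree=pedigree,
                          empty_generations=empty)


# ---------------------------------------------------------------------------
# sampling and genotyping error
# ---------------------------------------------------------------------------

def _observe_genotype(rng: np.random.Generator,
                      true_g: dict[str, tuple[int, int]],
                      freqs: FrequencyTable,
                      dropout_rate: float,
                      false_allele_rate: float,
                      locus_failure_rate: float) -> dict[str, tuple[int, int]]:
    obs: dict[str, tuple[int, int]] = {}
    for locus, (a, b) in true_g.items():
        if locus_failure_rate and rng.random() < locus_failure_rate:
            continue  # locus fails to amplify entirely
        pair = [a, b]
        # allelic dropout: per-allele loss; a heterozygote with one lost
        # allele reads as a false homozygote of the surviving allele
        if a != b and dropout_rate:
            drop_a = rng.random() < dropout_rate
            drop_b = rng.random() < dropout_rate
            if drop_a and drop_b:
                continue  # nothing amplifies
            if drop_a:
                pair = [b, b]
            elif drop_b:
                pair = [a, a]
        # false alleles: per-allele substitution by a random different allele
        if false_allele_rate:
            alleles = freqs.alleles(locus)
            if len(alleles) > 1:
                for i in range(2):
                    if rng.random() < false_allele_rate:
                        others = [x for x in alleles if x != pair[i]]
                        pair[i] = int(others[int(rng.integers(len(others)))])
        obs[locus] = (min(pair), max(pair))
    return obs


def apply_sampling_and_error(pop: TruePopulation, config: SimulationConfig,
                             freqs: FrequencyTable | None = None,
                             year: int = 2016,
                             source: str = "fecal") -> list[GenotypeObservation]:
    """Apply partial sampling and genotyping error to the true population.

    Individuals enter the sample independently with probability
    ``sampling_fraction``; a ``replicate_fraction`` of the sampled ones are
    amplified twice (independent error draws), emulating re-amplification
    of profiles for error-rate estimation.  Error processes per allele:
    dropout (heterozygote reads as false homozygote) and false alleles
    (substitution by a random different allele at the locus).
    """
    if freqs is None:
        # fall back to the allele sets actually present, weighted uniformly
        alleles: dict[str, set[int]] = {}
        for ind in pop.individuals.values():
            for locus, pair in ind.genotype.items():
                alleles.setdefault(locus, set()).update(pair)
        freqs = FrequencyTable.from_dict(
            {locus: {a: 1.0 / len(als) for a in als}
             for locus, als in alleles.items()})
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 911]))
    samples: list[GenotypeObservation] = []
    n = 0
    for iid in sorted(pop.individuals):
        ind = pop.individuals[iid]
        if rng.random() >= config.sampling_fraction:
            continue
        n_reps = 2 if rng.random() < config.replicate_fraction else 1
        for rep in range(1, n_reps + 1):
            n += 1
            obs = _observe_genotype(rng, ind.genotype, freqs,
                                    config.dropout_rate,
                                    config.false_allele_rate,
                                    config.locus_failure_rate)
            samples.append(GenotypeObservation(
                sample_id=f"S{n:05d}" + (f"r{rep}" if n_reps > 1 else ""),
                true_individual_id=iid,
                stratum=ind.natal_area,
                year=year,
                source=source,
                sex=ind.sex,
                x=ind.x,
                y=ind.y,
                genotype=obs,
            ))
    return samples


# ---------------------------------------------------------------------------
# writers (genotype CSV schema is defined by the pipeline layer)
# ---------------------------------------------------------------------------

def write_genotype_csv(samples: Sequence[GenotypeObservation], path,
                       loci: Sequence[str] | None = None) -> None:
    """Write samples in the pipeline genotype schema: one row per sample,
    two allele columns per locus, empty cell = missing."""
    if loci is None:
        seen: dict[str, None] = {}
        for s in samples:
            for locus in s.genotype:
                seen.setdefault(locus)
        loci = sorted(seen)
    header = ["sample_id", "area", "year", "source", "sex", "x", "y"]
    for locus in loci:
        header += [f"{locus}_a1", f"{locus}_a2"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for s in samples:
            row = [s.sample_id, s.stratum, s.year, s.source, s.sex,
                   repr(s.x), repr(s.y)]
            for locus in loci:
                pair = s.genotype.get(locus)
                row += ["", ""] if pair is None else [pair[0], pair[1]]
            w.writerow(row)


def write_pedigree_csv(pop: TruePopulation, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["offspring_id", "dam_id", "sire_id", "generation"])
        for off in sorted(pop.pedigree):
            dam, sire = pop.pedigree[off]
            w.writerow([off, dam, sire, pop.individuals[off].generation])
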
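"""Parent-offspring assignment from multilocus genotypes.

A two-stage assignment: a Mendelian exclusion pre-filter (candidates
sharing no allele with the offspring at more than ``max_exclusions``
comparable loci are discarded) followed by a joint transmission likelihood
over candidate (dam, sire) configurations, with a prior probability that a
true parent is among the sampled candidates (default 50%).  Offspring whose
best configuration leaves a parental slot empty receive inferred-parent
placeholders; placeholders are then greedily merged into shared inferred
parents where a single parental genotype is consistent with all grouped
offspring.  Polygamy is the default mating model and no inbreeding
avoidance is applied.

The likelihood treats each observed allele as the true allele with
probability 1 - e, or a random allele drawn from the population frequency
with probability e; unknown parents are marginalised over Hardy-Weinberg
genotype probabilities.  This is a deliberately transparent pairwise
stand-in for full-likelihood sibship reconstruction: it preserves the
semantics of the pedigree (every individual ends with exactly one dam and
one sire, sampled or inferred, and fitness equals offspring count) while
remaining exactly testable against enumeration oracles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import Individual
from .simulate import FrequencyTable

__all__ = [
    "ParentageConfig",
    "PedigreeTable",
    "locus_exclusions",
    "parentage_likelihood",
    "assign_parentage",
    "reconstruct_unsampled_parents",
    "fitness_counts",
]

NEG_INF = float("-inf")

Genotype = Mapping[str, tuple[int, int]]


@dataclass(frozen=True)
class ParentageConfig:
    error_rate: float = 0.01          # per-allele genotyping error in the likelihood
    max_exclusions: int = 1           # tolerated mismatching loci in the pre-filter
    prob_parent_sampled: float = 0.5  # prior that a true parent is a candidate
    allow_polygamy: bool = True
    inbreeding_avoidance: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if not 0.0 <= self.prob_parent_sampled <= 1.0:
            raise ValueError("prob_parent_sampled must be in [0, 1]")
        if self.max_exclusions < 0:
            raise ValueError("max_exclusions must be >= 0")


@dataclass
class PedigreeTable:
    """Rows (offspring, dam, sire) with sampled flags and a confidence
    score (log-likelihood margin of the winning configuration)."""

    df: pd.DataFrame
    inferred_sex: dict[str, str] = field(default_factory=dict)

    COLUMNS = ("offspring_id", "dam_id", "sire_id",
               "dam_sampled", "sire_sampled", "confidence")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"pedigree table missing columns {sorted(missing)}")
        if self.df["offspring_id"].duplicated().any():
            dupes = self.df.loc[self.df["offspring_id"].duplicated(), "offspring_id"]
            raise ValueError(f"offspring repeated in pedigree: {sorted(set(dupes))}")

    def __len__(self) -> int:
        return len(self.df)

    def parents_of(self, offspring_id: str) -> tuple[str, str]:
        row = self.df.loc[self.df["offspring_id"] == offspring_id].iloc[0]
        return row["dam_id"], row["sire_id"]

    def inferred_parents(self) -> list[str]:
        out = []
        for _, row in self.df.iterrows():
            if not row["dam_sampled"]:
                out.append(row["dam_id"])
            if not row["sire_sampled"]:
                out.append(row["sire_id"])
        return sorted(set(out))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "PedigreeTable":
        df = pd.read_csv(path, dtype={"offspring_id": str, "dam_id": str,
                                      "sire_id": str})
        df["dam_sampled"] = df["dam_sampled"].astype(bool)
        df["sire_sampled"] = df["sire_sampled"].astype(bool)
        return cls(df)


# ---------------------------------------------------------------------------
# exclusion pre-filter
# ---------------------------------------------------------------------------

def locus_exclusions(offspring: Genotype, candidate: Genotype) -> int:
    """Number of comparable loci at which the candidate parent shares no
    allele with the offspring (a Mendelian exclusion).  Missing loci are
    skipped; an empty comparable set returns 0 with a warning."""
    comparable = 0
    exclusions = 0
    for locus, pair in offspring.items():
        cand = candidate.get(locus)
        if cand is None:
            continue
        comparable += 1
        if pair[0] not in cand and pair[1] not in cand:
            exclusions += 1
    if comparable == 0:
        warnings.warn("no comparable loci between offspring and candidate",
                      stacklevel=2)
    return exclusions


def _exclusion_matrix(offspring: list[Individual], candidates: list[Individual],
                      loci: list[str]) -> np.ndarray:
    """Vectorised exclusion counts: (n_offspring, n_candidates)."""
    def encode(inds: list[Individual]) -> np.ndarray:
        arr = np.full((len(inds), len(loci), 2), -1, dtype=np.int32)
        idx = {locus: j for j, locus in enumerate(loci)}
        for i, ind in enumerate(inds):
            for locus, (a, b) in ind.genotype.items():
                if locus in idx:
                    arr[i, idx[locus]] = (a, b)
        return arr

    off = encode(offspring)       # (n, L, 2)
    cand = encode(candidates)     # (m, L, 2)
    typed_off = off[:, :, 0] >= 0
    typed_cand = cand[:, :, 0] >= 0
    n, m, L = len(offspring), len(candidates), len(loci)
    out = np.zeros((n, m), dtype=np.int32)
    block = max(1, int(2e7 // max(m * L, 1)))
    for s in range(0, n, block):
        e = min(s + block, n)
        o = off[s:e]
        share = np.zeros((e - s, m, L), dtype=bool)
        for i in range(2):
            for j in range(2):
                share |= o[:, None, :, i] == cand[None, :, :, j]
        comparable = typed_off[s:e, None] & typed_cand[None, :]
        out[s:e] = np.sum(comparable & ~share, axis=2)
    return out


# ---------------------------------------------------------------------------
# transmission likelihood
# ---------------------------------------------------------------------------

def _p_obs(o: int, t: int, eps: float, f: Mapping[int, float]) -> float:
    # observed allele = true allele w.p. 1-eps, or a frequency-weighted
    # random allele w.p. eps
    return (1.0 - eps) * (1.0 if o == t else 0.0) + eps * f.get(o, 0.0)


def _pair_obs_prob(obs: tuple[int, int], u: int, v: int, eps: float,
                   f: Mapping[int, float]) -> float:
    x, y = obs
    if x == y:
        return _p_obs(x, u, eps, f) * _p_obs(x, v, eps, f)
    return (_p_obs(x, u, eps, f) * _p_obs(y, v, eps, f)
            + _p_obs(y, u, eps, f) * _p_obs(x, v, eps, f))


def parentage_likelihood(offspring: Genotype,
                         dam: Genotype | None,
                         sire: Genotype | None,
                         freqs: FrequencyTable,
                         error_rate: float) -> float:
    """Log-likelihood of the offspring genotype under a (dam, sire)
    configuration.

    Per locus, the offspring receives one allele from each parental slot:
    from a stated parent, either of its two observed alleles with equal
    probability; from an unknown parent, an allele drawn from the
    population frequencies (the Hardy-Weinberg marginal of the transmitted
    allele).  The observed offspring pair is related to the transmitted
    pair through the per-allele error model.  Loci multiply (logs add);
    missing loci are skipped.  With ``error_rate`` = 0 a Mendelian
    impossibility yields -inf.
    """
    table = freqs.as_dict()
    total = 0.0
    for locus, obs in offspring.items():
        f = table.get(locus)
        if f is None:
            continue
        dam_alleles = (dam.get(locus) if dam is not None else None)
        sire_alleles = (sire.get(locus) if sire is not None else None)
        if dam_alleles is not None:
            dam_src = [(dam_alleles[0], 0.5), (dam_alleles[1], 0.5)]
        else:
            dam_src = list(f.items())
        if sire_alleles is not None:
            sire_src = [(sire_alleles[0], 0.5), (sire_alleles[1], 0.5)]
        else:
            sire_src = list(f.items())
        lik = 0.0
        for u, pu in dam_src:
            for v, pv in sire_src:
                lik += pu * pv * _pair_obs_prob(obs, u, v, error_rate, f)
        if lik <= 0.0:
            return NEG_INF
        total += math.log(lik)
    return total


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def _log(p: float) -> float:
    return math.log(p) if p > 0 else NEG_INF


def assign_parentage(individuals: Sequence[Individual],
                     freqs: FrequencyTable,
                     config: ParentageConfig = ParentageConfig()) -> PedigreeTable:
    """Assign one dam and one sire (sampled or inferred) to every
    individual.

    All sampled females are candidate dams and all sampled males candidate
    sires for every other individual.  Candidates failing the exclusion
    pre-filter are dropped; the remaining (dam, sire), (dam, unknown),
    (unknown, sire) and (unknown, unknown) configurations are scored by
    transmission log-likelihood plus a prior of ``prob_parent_sampled``
    per filled slot (1 - prob per unknown slot).  The winner fills the
    pedigree row; unknown slots become per-offspring inferred placeholders,
    to be merged by :func:`reconstruct_unsampled_parents`.  Orientation
    cycles (two individuals each assigned as the other's parent) are broken
    afterwards by discarding the lower-confidence edge with a warning.
    """
    inds = sorted(individuals, key=lambda i: i.individual_id)
    loci = sorted({locus for ind in inds for locus in ind.genotype})
    dams = [i for i in inds if i.sex == "F"]
    sires = [i for i in inds if i.sex == "M"]
    excl_dam = _exclusion_matrix(inds, dams, loci)
    excl_sire = _exclusion_matrix(inds, sires, loci)

    p = config.prob_parent_sampled
    log_p, log_q = _log(p), _log(1.0 - p)
    eps = config.error_rate

    rows = []
    skipped = []
    for oi, off in enumerate(inds):
        if not off.genotype:
            skipped.append(off.individual_id)
            continue
        cd = [d for di, d in enumerate(dams)
              if d.individual_id != off.individual_id
              and excl_dam[oi, di] <= config.max_exclusions]
        cs = [s for si, s in enumerate(sires)
              if s.individual_id != off.individual_id
              and excl_sire[oi, si] <= config.max_exclusions]

        # configurations: (dam or None, sire or None)
        best = None       # (score, dam_id or None, sire_id or None)
        second = NEG_INF
        def consider(score, d, s):
            nonlocal best, second
            key = (d.individual_id if d else "~", s.individual_id if s else "~")
            if best is None or score > best[0] or (score == best[0] and key < best[3]):
                if best is not None:
                    second = max(second, best[0])
                best = (score, d, s, key)
            else:
                second = max(second, score)

        base_unknown = parentage_likelihood(off.genotype, None, None, freqs, eps)
        consider(base_unknown + 2 * log_q, None, None)
        dam_only = {}
        for d in cd:
            ll = parentage_likelihood(off.genotype, d.genotype, None, freqs, eps)
            dam_only[d.individual_id] = ll
            consider(ll + log_p + log_q, d, None)
        sire_only = {}
        for s in cs:
            ll = parentage_likelihood(off.genotype, None, s.genotype, freqs, eps)
            sire_only[s.individual_id] = ll
            consider(ll + log_q + log_p, None, s)
        for d in cd:
            for s in cs:
                ll = parentage_likelihood(off.genotype, d.genotype, s.genotype,
                                          freqs, eps)
                consider(ll + 2 * log_p, d, s)

        score, d, s, _ = best
        oid = off.individual_id
        confidence = (score - second) if second > NEG_INF else float("inf")
        rows.append({
            "offspring_id": oid,
            "dam_id": d.individual_id if d else f"UD_{oid}",
            "sire_id": s.individual_id if s else f"US_{oid}",
            "dam_sampled": d is not None,
            "sire_sampled": s is not None,
            "confidence": confidence,
        })
    if skipped:
        warnings.warn(f"offspring with no typed loci excluded: {skipped}",
                      stacklevel=2)

    table = PedigreeTable(pd.DataFrame(rows, columns=list(PedigreeTable.COLUMNS)))
    _break_cycles(table)
    return table


def _break_cycles(table: PedigreeTable) -> None:
    """Discard the lower-confidence edge of every orientation cycle,
    replacing the offending parent with an inferred placeholder so the row
    stays complete.  Cycles arise when two individuals each select the
    other as a parent (typically a true parent-offspring pair whose roles
    cannot be told apart without age data); the higher-confidence
    orientation survives.  One summary warning reports the count."""
    import networkx as nx

    g = nx.DiGraph()
    conf = {}
    for _, row in table.df.iterrows():
        for slot in ("dam", "sire"):
            if row[f"{slot}_sampled"]:
                g.add_edge(row[f"{slot}_id"], row["offspring_id"])
                conf[(row[f"{slot}_id"], row["offspring_id"])] = row["confidence"]
    broken = []
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        worst = min(cycle, key=lambda e: (conf[(e[0], e[1])], e))
        parent, child = worst[0], worst[1]
        g.remove_edge(parent, child)
        broken.append((parent, child))
        mask = table.df["offspring_id"] == child
        for slot in ("dam", "sire"):
            sel = mask & (table.df[f"{slot}_id"] == parent)
            prefix = "UD" if slot == "dam" else "US"
            table.df.loc[sel, f"{slot}_id"] = f"{prefix}_{child}"
            table.df.loc[sel, f"{slot}_sampled"] = False
    if broken:
        warnings.warn(
            f"{len(broken)} pedigree orientation cycle(s) broken by "
            f"discarding the lower-confidence edge (first: "
            f"{broken[0][0]}->{broken[0][1]})", stacklevel=3)


# ---------------------------------------------------------------------------
# merging inferred parents (greedy sib grouping)
# ---------------------------------------------------------------------------

def _maternal_compatible(g1: Genotype, g2: Genotype) -> tuple[bool, int]:
    """Pairwise test that two offspring could share a parent: non-empty
    allele intersection at every comparable locus.  Returns (compatible,
    number of sharing loci) — the sharing count is the greedy score."""
    shared = 0
    for locus, p1 in g1.items():
        p2 = g2.get(locus)
        if p2 is None:
            continue
        if p1[0] in p2 or p1[1] in p2:
            shared += 1
        else:
            return False, shared
    return True, shared


def _group_cover_ok(genotypes: list[Genotype]) -> bool:
    """A group can descend from one parent only if, at every locus typed in
    >= 1 member, some parental genotype of <= 2 alleles transmits an allele
    carried by each typed member."""
    loci = sorted({locus for g in genotypes for locus in g})
    for locus in loci:
        pairs = [g[locus] for g in genotypes if locus in g]
        if len(pairs) <= 2:
            continue  # a 2-allele cover always exists for <= 2 members
        alleles = sorted({a for p in pairs for a in p})
        ok = any(all(u in p or v in p for p in pairs)
                 for ii, u in enumerate(alleles) for v in alleles[ii:])
        if not ok:
            return False
    return True


def reconstruct_unsampled_parents(pedigree: PedigreeTable,
                                  individuals: Sequence[Individual],
                                  freqs: FrequencyTable | None = None,
                                  config: ParentageConfig = ParentageConfig()
                                  ) -> PedigreeTable:
    """Merge per-offspring inferred placeholders into shared inferred
    parents.

    Separately for the dam and sire slots, offspring with placeholder
    parents are greedily agglomerated: candidate merges are ordered by
    descending allele-sharing score (number of comparable loci with a
    common allele), ties by lexicographic offspring id, and a merge is
    accepted only when every cross-group offspring pair shares an allele at
    every comparable locus and a single <= 2-allele parental genotype per
    locus remains consistent with the whole group.  Each final group's
    placeholders are replaced by one inferred individual (``INFD####`` /
    ``INFS####``), sex-typed by slot.
    """
    by_id = {i.individual_id: i for i in individuals}
    df = pedigree.df.copy()
    inferred_sex: dict[str, str] = {}

    for slot, prefix, sex in (("dam", "INFD", "F"), ("sire", "INFS", "M")):
        mask = ~df[f"{slot}_sampled"]
        offspring_ids = sorted(df.loc[mask, "offspring_id"])
        genos = {o: by_id[o].genotype if o in by_id else {} for o in offspring_ids}

        # initial singleton groups, then greedy best-score merging
        groups: dict[str, list[str]] = {o: [o] for o in offspring_ids}
        pair_scores = []
        for i, o1 in enumerate(offspring_ids):
            for o2 in offspring_ids[i + 1:]:
                ok, score = _maternal_compatible(genos[o1], genos[o2])
                if ok and score > 0:
                    pair_scores.append((-score, o1, o2))
        pair_scores.sort()

        leader = {o: o for o in offspring_ids}

        def find(o: str) -> str:
            while leader[o] != o:
                o = leader[o]
            return o

        for _, o1, o2 in pair_scores:
            r1, r2 = find(o1), find(o2)
            if r1 == r2:
                continue
            members = groups[r1] + groups[r2]
            ok = all(_maternal_compatible(genos[a], genos[b])[0]
                     for i, a in enumerate(members) for b in members[i + 1:])
            if ok and _group_cover_ok([genos[m] for m in members]):
                root, other = sorted((r1, r2))
                groups[root] = sorted(members)
                leader[other] = root
                del groups[other]

        for k, root in enumerate(sorted(groups)):
            pid = f"{prefix}{k + 1:04d}"
            inferred_sex[pid] = sex
            sel = df["offspring_id"].isin(groups[root]) & ~df[f"{slot}_sampled"]
            df.loc[sel, f"{slot}_id"] = pid

    return PedigreeTable(df, inferred_sex=inferred_sex)


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------

def fitness_counts(pedigree: PedigreeTable) -> dict[str, int]:
    """Offspring count per individual: the number of pedigree rows naming
    it as dam or sire (the reproductive-output fitness proxy)."""
    counts: dict[str, int] = {}
    for _, row in pedigree.df.iterrows():
        for col in ("dam_id", "sire_id"):
            counts[row[col]] = counts.get(row[col], 0) + 1
    return counts
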
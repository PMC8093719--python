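"""Sample consolidation and genotyping quality control.

Noninvasive genetic sampling (fecal pellets, blood blots) yields multiple
samples per animal with partial, error-prone multilocus profiles.  This
module turns raw genotype samples into unique individuals by single-linkage
matching with a mismatch tolerance, and computes the standard QC summary:
per-stratum genotyping success, allelic-dropout and false-allele rates
estimated from replicate re-amplifications.
"""

from __future__ import annotations

import csv
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import GenotypeObservation

__all__ = [
    "GenotypeSample",
    "Individual",
    "ConsolidationResult",
    "QCReport",
    "read_genotype_csv",
    "write_individuals_csv",
    "consolidate_individuals",
    "qc_summary",
    "success_percent",
    "unweighted_mean_percent",
    "estimate_allele_frequencies",
]

GenotypeSample = GenotypeObservation  # one field/lab sample; alias of the simulator's record


@dataclass
class Individual:
    """A consolidated unique genotype.

    ``sampled`` individuals carry >= 1 member sample and representative
    coordinates (the first member's, by sample id); inferred individuals
    created later during parentage have neither.
    """

    individual_id: str
    genotype: dict[str, tuple[int, int]]
    sex: str                      # 'F', 'M' or 'U'
    sampled: bool = True
    member_samples: list[str] = field(default_factory=list)
    x: float | None = None
    y: float | None = None
    area: str | None = None

    @property
    def n_typed_loci(self) -> int:
        return len(self.genotype)


@dataclass
class ConsolidationResult:
    individuals: list[Individual]
    sample_to_individual: dict[str, str]
    excluded_samples: list[str]            # < min_loci typed loci
    singletons: list[str]                  # individuals from a single sample
    warnings: list[str] = field(default_factory=list)

    def audit_lines(self) -> list[str]:
        lines = [f"retained {len(self.sample_to_individual)} samples into "
                 f"{len(self.individuals)} unique individuals"]
        lines += [f"excluded (too few loci): {s}" for s in self.excluded_samples]
        lines += [f"singleton (re-amplification review): {i}" for i in self.singletons]
        lines += self.warnings
        return lines


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_genotype_csv(path) -> list[GenotypeSample]:
    """Read the pipeline genotype schema (sample_id, area, year, source,
    sex, x, y, then ``<locus>_a1``/``<locus>_a2`` pairs; empty = missing)."""
    samples = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        loci = sorted({c[:-3] for c in reader.fieldnames or []
                       if c.endswith("_a1")})
        for row in reader:
            genotype = {}
            for locus in loci:
                a1, a2 = row.get(f"{locus}_a1", ""), row.get(f"{locus}_a2", "")
                if a1 != "" and a2 != "":
                    a, b = int(a1), int(a2)
                    genotype[locus] = (min(a, b), max(a, b))
            samples.append(GenotypeSample(
                sample_id=row["sample_id"],
                true_individual_id="",
                stratum=row.get("area", ""),
                year=int(row["year"]) if row.get("year") else 0,
                source=row.get("source", ""),
                sex=row.get("sex", "U") or "U",
                x=float(row["x"]) if row.get("x") else float("nan"),
                y=float(row["y"]) if row.get("y") else float("nan"),
                genotype=genotype,
            ))
    return samples


def write_individuals_csv(individuals: Sequence[Individual], path,
                          loci: Sequence[str] | None = None) -> None:
    if loci is None:
        loci = sorted({locus for ind in individuals for locus in ind.genotype})
    header = ["individual_id", "sex", "sampled", "x", "y", "area", "n_samples"]
    for locus in loci:
        header += [f"{locus}_a1", f"{locus}_a2"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for ind in individuals:
            row = [ind.individual_id, ind.sex, int(ind.sampled),
                   "" if ind.x is None else repr(ind.x),
                   "" if ind.y is None else repr(ind.y),
                   ind.area or "", len(ind.member_samples)]
            for locus in loci:
                pair = ind.genotype.get(locus)
                row += ["", ""] if pair is None else [pair[0], pair[1]]
            w.writerow(row)


# ---------------------------------------------------------------------------
# consolidation
# ---------------------------------------------------------------------------

def _pairwise_mismatches(samples: list[GenotypeSample],
                         loci: list[str]) -> np.ndarray:
    """Mismatch counts over comparable loci for every sample pair.

    Encodes each profile as an (n_loci, 2) integer array (missing = -1).
    A comparable locus where the unordered allele pairs differ scores a
    full mismatch, EXCEPT the single-dropout signature — one sample a
    homozygote whose allele appears in the other's pair — which scores
    half: it is weak evidence for two individuals, since one allelic
    dropout manufactures exactly this pattern.  Missing loci score
    nothing.
    """
    n, L = len(samples), len(loci)
    arr = np.full((n, L, 2), -1, dtype=np.int32)
    idx = {locus: j for j, locus in enumerate(loci)}
    for i, s in enumerate(samples):
        for locus, (a, b) in s.genotype.items():
            arr[i, idx[locus]] = (a, b)
    typed = arr[:, :, 0] >= 0                                   # (n, L)
    hom = arr[:, :, 0] == arr[:, :, 1]
    mism = np.zeros((n, n), dtype=float)
    # block the quadratic comparison to bound memory on large sample sets
    block = max(1, int(2e7 // max(n * L, 1)))
    for start in range(0, n, block):
        stop = min(start + block, n)
        a = arr[start:stop, None]                               # (b, 1, L, 2)
        b = arr[None, :]                                        # (1, n, L, 2)
        same = np.all(a == b, axis=3)
        a_in_b = ((a[..., 0] == b[..., 0]) | (a[..., 0] == b[..., 1]))
        b_in_a = ((b[..., 0] == a[..., 0]) | (b[..., 0] == a[..., 1]))
        dropoutish = ((hom[start:stop, None] & a_in_b)
                      | (hom[None, :] & b_in_a))
        comparable = typed[start:stop, None] & typed[None, :]
        differ = comparable & ~same
        mism[start:stop] = (np.sum(differ & ~dropoutish, axis=2)
                            + 0.5 * np.sum(differ & dropoutish, axis=2))
    return mism


def consolidate_individuals(samples: Sequence[GenotypeSample],
                            max_mismatch: int = 2,
                            min_loci: int = 5) -> ConsolidationResult:
    """Group samples into unique individuals.

    Samples typed at fewer than ``min_loci`` loci are excluded (reported,
    not silently dropped).  The rest are joined single-linkage on the
    mismatch graph: an edge wherever two profiles disagree at most
    ``max_mismatch`` comparable loci (missing loci are never counted as
    mismatches).  Each connected group becomes one individual with a
    majority-consensus genotype; allele-pair ties resolve toward the
    heterozygote, because dropout manufactures false homozygotes.
    Deterministic and order-independent: groups are processed and labelled
    by their lexicographically smallest sample id.
    """
    if min_loci < 1:
        raise ValueError("min_loci must be >= 1")
    ids = [s.sample_id for s in samples]
    dupes = [sid for sid, k in Counter(ids).items() if k > 1]
    if dupes:
        raise ValueError(f"duplicate sample ids: {sorted(dupes)}")

    order = sorted(range(len(samples)), key=lambda i: samples[i].sample_id)
    samples = [samples[i] for i in order]

    excluded = [s.sample_id for s in samples if len(s.genotype) < min_loci]
    kept = [s for s in samples if len(s.genotype) >= min_loci]
    loci = sorted({locus for s in kept for locus in s.genotype})

    result = ConsolidationResult([], {}, excluded, [])
    if not kept:
        return result

    mism = _pairwise_mismatches(kept, loci)
    adj = mism <= max_mismatch

    # single-linkage = connected components of the adjacency
    n = len(kept)
    labels = np.full(n, -1, dtype=int)
    group = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        stack = [i]
        labels[i] = group
        while stack:
            u = stack.pop()
            for v in np.nonzero(adj[u])[0]:
                if labels[v] < 0:
                    labels[v] = group
                    stack.append(int(v))
        group += 1

    for g in range(group):
        members = [kept[i] for i in np.nonzero(labels == g)[0]]
        members.sort(key=lambda s: s.sample_id)
        iid = f"IND{g + 1:05d}"
        genotype: dict[str, tuple[int, int]] = {}
        for locus in loci:
            pairs = [s.genotype[locus] for s in members if locus in s.genotype]
            if not pairs:
                continue
            counts = Counter(pairs)
            best = max(counts.values())
            tied = sorted([p for p, c in counts.items() if c == best],
                          key=lambda p: (p[0] == p[1], p))  # heterozygotes first
            genotype[locus] = tied[0]
        sexes = Counter(s.sex for s in members if s.sex in ("F", "M"))
        if not sexes:
            sex = "U"
        elif len(sexes) > 1 and len(set(sexes.values())) == 1:
            sex = "U"
            result.warnings.append(f"sex conflict in {iid}: {dict(sexes)}")
        else:
            sex = sexes.most_common(1)[0][0]
            if len(sexes) > 1:
                result.warnings.append(f"sex conflict in {iid}: {dict(sexes)}")
        first = members[0]
        ind = Individual(individual_id=iid, genotype=genotype, sex=sex,
                         sampled=True,
                         member_samples=[s.sample_id for s in members],
                         x=first.x, y=first.y, area=first.stratum)
        result.individuals.append(ind)
        for s in members:
            result.sample_to_individual[s.sample_id] = iid
        if len(members) == 1:
            result.singletons.append(iid)
    return result


# ---------------------------------------------------------------------------
# QC summary
# ---------------------------------------------------------------------------

def success_percent(collected: int, scored: int) -> float | None:
    """Genotyping success as scored/collected x 100 (1 decimal);
    undefined (None) when nothing was collected."""
    if collected == 0:
        return None
    if scored > collected:
        raise ValueError("scored cannot exceed collected")
    return round(scored / collected * 100.0, 1)


def unweighted_mean_percent(values: Iterable[float]) -> float:
    """Unweighted mean of stratum percentages, 1 decimal."""
    vals = [v for v in values if v is not None]
    if not vals:
        raise ValueError("no defined percentages to average")
    return round(sum(vals) / len(vals), 1)


@dataclass
class QCReport:
    per_stratum: pd.DataFrame     # columns: stratum, collected, scored, unique, success_pct, dropout_pct, false_allele_pct
    overall_collected: int
    overall_scored: int
    overall_unique: int
    mean_success_pct: float | None

    def to_csv(self, path) -> None:
        self.per_stratum.to_csv(path, index=False)


def _replicate_error_counts(s1: GenotypeSample, s2: GenotypeSample):
    """Dropout / false-allele discordance counts for one replicate pair.

    At each comparable locus: a het-vs-hom discordance whose homozygous
    allele belongs to the heterozygous pair is a dropout event, with the
    heterozygous genotypes contributing the at-risk allele observations;
    any allele seen in one replicate but absent from the other and not
    explained as dropout counts as a false-allele event over all four
    allele observations at the locus.
    """
    dropouts = het_obs = false = allele_obs = 0
    for locus in set(s1.genotype) & set(s2.genotype):
        p1, p2 = s1.genotype[locus], s2.genotype[locus]
        h1, h2 = p1[0] != p1[1], p2[0] != p2[1]
        het_obs += 2 * (h1 + h2)
        allele_obs += 4
        if p1 == p2:
            continue
        if h1 and not h2 and p2[0] in p1:
            dropouts += 1
        elif h2 and not h1 and p1[0] in p2:
            dropouts += 1
        else:
            novel = [a for a in p1 if a not in p2] + [a for a in p2 if a not in p1]
            false += len(set(novel))
    return dropouts, het_obs, false, allele_obs


def qc_summary(samples: Sequence[GenotypeSample],
               scored: Mapping[str, bool],
               replicate_pairs: Iterable[tuple[str, str]] = (),
               unique_of: Mapping[str, str] | None = None) -> QCReport:
    """Per-stratum and overall QC statistics.

    ``scored`` flags which samples produced a usable profile; ``unique_of``
    (sample id -> individual id, from consolidation) supplies the
    unique-genotype counts; ``replicate_pairs`` are re-amplified sample
    pairs of the same individual used to estimate dropout and false-allele
    rates.  Success % is scored/collected x 100 per stratum; the overall
    figure is the unweighted mean of the stratum percentages.
    """
    by_id = {s.sample_id: s for s in samples}
    if unique_of:
        for a, b in replicate_pairs:
            if unique_of.get(a) != unique_of.get(b):
                raise ValueError(f"replicate pair ({a}, {b}) spans two individuals")

    strata = sorted({s.stratum for s in samples})
    rows = []
    err: dict[str, list[int]] = {st: [0, 0, 0, 0] for st in strata}
    for a, b in replicate_pairs:
        sa, sb = by_id[a], by_id[b]
        d, h, f, t = _replicate_error_counts(sa, sb)
        tallies = err[sa.stratum]
        tallies[0] += d
        tallies[1] += h
        tallies[2] += f
        tallies[3] += t
    for st in strata:
        coll = [s for s in samples if s.stratum == st]
        sc = [s for s in coll if scored.get(s.sample_id, False)]
        uniq = (len({unique_of[s.sample_id] for s in sc
                     if s.sample_id in unique_of}) if unique_of else None)
        d, h, f, t = err[st]
        rows.append({
            "stratum": st,
            "collected": len(coll),
            "scored": len(sc),
            "unique": uniq,
            "success_pct": success_percent(len(coll), len(sc)),
            "dropout_pct": round(d / h * 100.0, 4) if h else None,
            "false_allele_pct": round(f / t * 100.0, 4) if t else None,
        })
    per_stratum = pd.DataFrame(rows)
    defined = [r["success_pct"] for r in rows if r["success_pct"] is not None]
    return QCReport(
        per_stratum=per_stratum,
        overall_collected=len(samples),
        overall_scored=sum(1 for s in samples if scored.get(s.sample_id, False)),
        overall_unique=(len(set(unique_of.values())) if unique_of else 0),
        mean_success_pct=unweighted_mean_percent(defined) if defined else None,
    )


# ---------------------------------------------------------------------------
# allele frequencies from consolidated individuals
# ---------------------------------------------------------------------------

def estimate_allele_frequencies(individuals: Sequence[Individual]):
    """Observed population allele frequencies from consolidated genotypes
    (each typed individual contributes its two alleles per locus)."""
    from .simulate import FrequencyTable

    counts: dict[str, Counter] = {}
    for ind in individuals:
        for locus, pair in ind.genotype.items():
            counts.setdefault(locus, Counter()).update(pair)
    table = {}
    for locus, c in counts.items():
        total = sum(c.values())
        table[locus] = {a: k / total for a, k in sorted(c.items())}
    if not table:
        raise ValueError("no typed loci among individuals")
    return FrequencyTable.from_dict(table)
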
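"""Synthetic multigroup primate populations with known ground truth.

Generates the four kinds of data the downstream analyses consume, with the
true pedigree and dispersal history recorded so every inference stage can be
scored against truth:

* a multigroup pedigree with obligate male natal dispersal, facultative
  (optionally parallel) female dispersal, and occasional group fission along
  matrilines;
* diploid short-tandem-repeat (STR) genotypes inherited Mendelian-ly at each
  locus, with missing calls applied last (mimicking fecal-DNA dropout);
* instantaneous scan samples recording which group mates sat within one
  meter of a focal animal, with an optional female-female assortment effect;
* right-censored group-tenure records split into natal and breeding context.

Time is measured in months throughout.  Generations are non-overlapping for
breeding purposes (each cohort breeds exactly once, with the opposite-sex
pool resident in its group at the breeding date), but all individuals remain
alive and observable to the end of the study, so groups contain several
generations at once.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PopulationConfig",
    "Individual",
    "GenotypeTable",
    "Population",
    "ScanDataset",
    "simulate_population",
    "simulate_scans",
    "simulate_tenures",
    "load_config",
    "write_genepop",
]

# -- fixed life-history constants (months) ---------------------------------

GENERATION_INTERVAL = 96.0
#: age-class cutoffs: males adult past 7 y, females past 5 y, subadult from 3 y
MALE_ADULT_AGE = 84.0
FEMALE_ADULT_AGE = 60.0
SUBADULT_AGE = 36.0
#: natal dispersal age windows (uniform draws)
MALE_DISPERSAL_AGE_MIN = 37.0
FEMALE_DISPERSAL_AGE_RANGE = (48.0, 72.0)

MISSING = -1


@dataclass(frozen=True)
class PopulationConfig:
    """Parameters of the synthetic population.

    Probabilities are per-individual (dispersal) or per-group-per-generation
    (fission).  ``parallel_dispersal_prob`` is the probability, given that a
    female disperses, that she takes her co-resident daughters and sisters
    along as a cohort.  ``status_known_prob`` is the fraction of animals
    whose dispersal status is revealed to the analyst (emulating animals
    whose immigration or philopatry was directly observed).
    """

    n_groups: int = 8
    founders_per_group: int = 7
    n_generations: int = 2
    n_loci: int = 20
    alleles_per_locus: int = 8
    allele_freq_concentration: float = 1.0
    female_dispersal_prob: float = 0.5
    parallel_dispersal_prob: float = 0.5
    fission_prob_per_generation: float = 0.1
    male_dispersal_age_months: float = 84.0
    genotype_missing_rate: float = 0.05
    offspring_per_female: int = 2
    status_known_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_groups", "founders_per_group", "n_generations",
                     "n_loci", "alleles_per_locus", "offspring_per_female"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("female_dispersal_prob", "parallel_dispersal_prob",
                     "fission_prob_per_generation", "genotype_missing_rate",
                     "status_known_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.male_dispersal_age_months <= 0:
            raise ValueError("male_dispersal_age_months must be positive")
        if self.allele_freq_concentration <= 0:
            raise ValueError("allele_freq_concentration must be positive")


def load_config(path) -> PopulationConfig:
    """Read a ``PopulationConfig`` from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PopulationConfig(**raw)


@dataclass
class Individual:
    id: str
    sex: str                      # "F" | "M"
    birth_group: str
    mother_id: str | None
    father_id: str | None
    birth_time: float
    generation: int
    current_group: str = ""
    entry_time: float = 0.0       # entry into current group
    exit_time: float | None = None  # None = censored at study end
    known_status: str = "unknown"   # "natal" | "immigrant" | "unknown"

    @property
    def true_status(self) -> str:
        return "natal" if self.current_group == self.birth_group else "immigrant"

    def age_at(self, t: float) -> float:
        return t - self.birth_time

    def age_class_at(self, t: float) -> str:
        age = self.age_at(t)
        adult = MALE_ADULT_AGE if self.sex == "M" else FEMALE_ADULT_AGE
        if age > adult:
            return "adult"
        if age >= SUBADULT_AGE:
            return "subadult"
        return "juvenile"


class GenotypeTable:
    """Diploid STR calls: an (individuals x loci x 2) integer array.

    Allele labels are positive integers; ``-1`` marks a missing call (both
    gene copies of a locus are missing together, as in a failed amplification).
    """

    def __init__(self, ids: Sequence[str], loci: Sequence[str], calls: np.ndarray):
        calls = np.asarray(calls, dtype=np.int64)
        if calls.shape != (len(ids), len(loci), 2):
            raise ValueError("calls must have shape (n_individuals, n_loci, 2)")
        self.ids = list(ids)
        self.loci = list(loci)
        self.calls = calls
        self._row = {i: k for k, i in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def genotype(self, individual: str, locus: str) -> tuple[int, int] | None:
        a, b = self.calls[self._row[individual], self.loci.index(locus)]
        if a == MISSING:
            return None
        return int(a), int(b)

    def typed_mask(self) -> np.ndarray:
        """Boolean (n, L): locus typed in that individual."""
        return self.calls[:, :, 0] != MISSING

    def n_loci_typed(self) -> dict[str, int]:
        counts = self.typed_mask().sum(axis=1)
        return {i: int(c) for i, c in zip(self.ids, counts)}

    def subset(self, ids: Iterable[str]) -> "GenotypeTable":
        ids = [i for i in ids if i in self._row]
        rows = [self._row[i] for i in ids]
        return GenotypeTable(ids, self.loci, self.calls[rows])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, ind in enumerate(self.ids):
            for j, locus in enumerate(self.loci):
                a, b = self.calls[k, j]
                rows.append((ind, locus,
                             "" if a == MISSING else int(a),
                             "" if b == MISSING else int(b)))
        return pd.DataFrame(rows, columns=["id", "locus", "allele1", "allele2"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeTable":
        ids = list(dict.fromkeys(df["id"]))
        loci = list(dict.fromkeys(df["locus"]))
        calls = np.full((len(ids), len(loci), 2), MISSING, dtype=np.int64)
        row = {i: k for k, i in enumerate(ids)}
        col = {l: j for j, l in enumerate(loci)}
        for rec in df.itertuples(index=False):
            a1, a2 = rec.allele1, rec.allele2
            if pd.isna(a1) or a1 == "" or pd.isna(a2) or a2 == "":
                continue
            calls[row[rec.id], col[rec.locus]] = (int(a1), int(a2))
        return cls(ids, loci, calls)

    @classmethod
    def from_csv(cls, path) -> "GenotypeTable":
        return cls.from_frame(pd.read_csv(path))


def write_genepop(genotypes: GenotypeTable, path, title: str = "synthetic population") -> None:
    """Write a GenePop-style text file (two 3-digit codes per locus)."""
    buf = io.StringIO()
    buf.write(title + "\n")
    for locus in genotypes.loci:
        buf.write(locus + "\n")
    buf.write("Pop\n")
    for k, ind in enumerate(genotypes.ids):
        fields = []
        for j in range(len(genotypes.loci)):
            a, b = genotypes.calls[k, j]
            if a == MISSING:
                fields.append("000000")
            else:
                fields.append(f"{a:03d}{b:03d}")
        buf.write(f"{ind}, " + " ".join(fields) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


@dataclass
class Population:
    """A simulated population: individuals, genotypes, and history."""

    config: PopulationConfig
    individuals: dict[str, Individual]
    genotypes: GenotypeTable
    membership: pd.DataFrame          # columns: individual, group, start, end ('' = open)
    allele_frequencies_true: dict[str, dict[int, float]]
    groups: list[str]
    study_end: float

    def offspring_map(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {i: set() for i in self.individuals}
        for ind in self.individuals.values():
            for parent in (ind.mother_id, ind.father_id):
                if parent is not None:
                    out[parent].add(ind.id)
        return out

    def sexes(self) -> dict[str, str]:
        return {i: ind.sex for i, ind in self.individuals.items()}

    def current_groups(self) -> dict[str, str]:
        return {i: ind.current_group for i, ind in self.individuals.items()}

    def age_classes(self, at: float | None = None) -> dict[str, str]:
        t = self.study_end if at is None else at
        return {i: ind.age_class_at(t) for i, ind in self.individuals.items()}

    def members_of(self, group: str) -> list[str]:
        return sorted(i for i, ind in self.individuals.items() if ind.current_group == group)

    def pedigree_dyads(self) -> pd.DataFrame:
        """All parent-offspring and full-sibling dyads with their relation.

        Used to draw "known kin" sets for threshold calibration.
        """
        rows = []
        inds = self.individuals
        for ind in inds.values():
            for parent in (ind.mother_id, ind.father_id):
                if parent is not None:
                    a, b = sorted((ind.id, parent))
                    rows.append((a, b, "parent_offspring"))
        by_parents: dict[tuple[str, str], list[str]] = {}
        for ind in inds.values():
            if ind.mother_id is not None and ind.father_id is not None:
                by_parents.setdefault((ind.mother_id, ind.father_id), []).append(ind.id)
        for sibs in by_parents.values():
            for i in range(len(sibs)):
                for j in range(i + 1, len(sibs)):
                    a, b = sorted((sibs[i], sibs[j]))
                    rows.append((a, b, "full_sib"))
        return pd.DataFrame(sorted(set(rows)), columns=["id1", "id2", "relation"])

    def demography_frame(self) -> pd.DataFrame:
        rows = []
        for ind in sorted(self.individuals.values(), key=lambda x: x.id):
            rows.append({
                "id": ind.id, "sex": ind.sex,
                "age_class": ind.age_class_at(self.study_end),
                "birth_group": ind.birth_group, "current_group": ind.current_group,
                "mother_id": ind.mother_id or "", "father_id": ind.father_id or "",
                "birth_time": ind.birth_time, "entry_time": ind.entry_time,
                "exit_time": "" if ind.exit_time is None else ind.exit_time,
                "generation": ind.generation,
                "true_status": ind.true_status, "known_status": ind.known_status,
            })
        return pd.DataFrame(rows)

    def matriline_root(self, individual: str) -> str:
        ind = self.individuals[individual]
        while ind.mother_id is not None:
            ind = self.individuals[ind.mother_id]
        return ind.id


# -- pedigree simulation ----------------------------------------------------


def _draw_founder_frequencies(rng, config) -> dict[str, dict[int, float]]:
    freqs = {}
    for j in range(config.n_loci):
        p = rng.dirichlet(np.full(config.alleles_per_locus,
                                  config.allele_freq_concentration))
        freqs[f"L{j + 1:02d}"] = {a + 1: float(p[a]) for a in range(config.alleles_per_locus)}
    return freqs


def simulate_population(config: PopulationConfig) -> Population:
    """Simulate the pedigree, dispersal history, and STR genotypes.

    Reproducible: identical config (including seed) gives byte-identical
    outputs.  Males always leave their birth group before
    ``male_dispersal_age_months``; females leave with probability
    ``female_dispersal_prob`` around five years of age, sometimes taking a
    kin cohort along; groups fission along matrilines.
    """
    rng = np.random.default_rng(config.seed)
    loci = [f"L{j + 1:02d}" for j in range(config.n_loci)]
    true_freqs = _draw_founder_frequencies(rng, config)

    groups = [f"G{g + 1}" for g in range(config.n_groups)]
    individuals: dict[str, Individual] = {}
    stints: list[list] = []   # [individual, group, start, end|None]
    open_stint: dict[str, int] = {}
    genotype_of: dict[str, np.ndarray] = {}
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"I{counter:04d}"

    def add_individual(ind: Individual, genotype: np.ndarray) -> None:
        individuals[ind.id] = ind
        genotype_of[ind.id] = genotype
        open_stint[ind.id] = len(stints)
        stints.append([ind.id, ind.current_group, ind.entry_time, None])

    def move(ind: Individual, dest: str, when: float) -> None:
        stints[open_stint[ind.id]][3] = when
        ind.current_group = dest
        ind.entry_time = when
        open_stint[ind.id] = len(stints)
        stints.append([ind.id, dest, when, None])

    # founders: alternating sexes so every group starts with both
    for g in groups:
        for k in range(config.founders_per_group):
            sex = "F" if k % 2 == 0 else "M"
            geno = np.empty((config.n_loci, 2), dtype=np.int64)
            for j, locus in enumerate(loci):
                labels = np.array(sorted(true_freqs[locus]))
                p = np.array([true_freqs[locus][a] for a in labels])
                geno[j] = rng.choice(labels, size=2, p=p)
            ind = Individual(id=new_id(), sex=sex, birth_group=g, mother_id=None,
                             father_id=None, birth_time=0.0, generation=0,
                             current_group=g, entry_time=0.0)
            add_individual(ind, geno)

    def mendelian_child(mother: str, father: str) -> np.ndarray:
        gm, gf = genotype_of[mother], genotype_of[father]
        pick_m = rng.integers(0, 2, size=config.n_loci)
        pick_f = rng.integers(0, 2, size=config.n_loci)
        child = np.stack([gm[np.arange(config.n_loci), pick_m],
                          gf[np.arange(config.n_loci), pick_f]], axis=1)
        return child

    for gen in range(1, config.n_generations + 1):
        t_breed = gen * GENERATION_INTERVAL
        cohort = [i for i in individuals.values() if i.generation == gen - 1]

        # 1. natal dispersal of the breeding cohort, in chronological order
        events = []  # (time, id, kind)
        for ind in sorted(cohort, key=lambda x: x.id):
            if ind.sex == "M":
                lo = min(MALE_DISPERSAL_AGE_MIN, config.male_dispersal_age_months)
                age = rng.uniform(lo, config.male_dispersal_age_months)
                events.append((ind.birth_time + age, ind.id, "M"))
            else:
                if rng.random() < config.female_dispersal_prob:
                    age = rng.uniform(*FEMALE_DISPERSAL_AGE_RANGE)
                    events.append((ind.birth_time + age, ind.id, "F"))
        moved: set[str] = set()
        for when, iid, kind in sorted(events):
            if iid in moved:
                continue
            ind = individuals[iid]
            others = [g for g in groups if g != ind.current_group]
            if not others:   # single-group population: nowhere to go
                continue
            dest = others[rng.integers(len(others))]
            movers = [ind]
            if kind == "F" and rng.random() < config.parallel_dispersal_prob:
                # parallel cohort: co-resident sisters and daughters
                for other in sorted(cohort, key=lambda x: x.id):
                    if (other.id != iid and other.sex == "F"
                            and other.id not in moved
                            and other.current_group == ind.current_group
                            and other.mother_id is not None
                            and other.mother_id == ind.mother_id):
                        movers.append(other)
                for child_id in sorted(individuals):
                    child = individuals[child_id]
                    if (child.mother_id == iid and child.sex == "F"
                            and child.id not in moved
                            and child.current_group == ind.current_group):
                        movers.append(child)
            for m in movers:
                move(m, dest, when)
                moved.add(m.id)

        # 2. fission along matrilines
        for g in list(groups):
            if rng.random() >= config.fission_prob_per_generation:
                continue
            members = [individuals[i] for i in sorted(individuals)
                       if individuals[i].current_group == g]
            roots = sorted({_matriline_root(individuals, m.id) for m in members})
            if len(roots) < 2:
                continue
            order = list(rng.permutation(len(roots)))
            leaving_roots = {roots[k] for k in order[: len(roots) // 2]}
            new_group = f"G{len(groups) + 1}"
            groups.append(new_group)
            for m in members:
                if _matriline_root(individuals, m.id) in leaving_roots:
                    move(m, new_group, t_breed - 0.5)

        # make sure every group has at least one prospective father
        males = [i for i in cohort if i.sex == "M"]
        if males:
            def males_in(g):
                return [m for m in males if m.current_group == g]
            for g in groups:
                if not males_in(g):
                    donors = [m for m in males
                              if len(males_in(m.current_group)) > 1 and m.birth_group != g]
                    if donors:
                        donor = donors[rng.integers(len(donors))]
                        move(donor, g, t_breed - 0.25)

        # 3. births: cohort females breed with co-resident cohort males
        for g in list(groups):
            mothers = [i for i in cohort if i.sex == "F" and i.current_group == g]
            fathers = [i for i in cohort if i.sex == "M" and i.current_group == g]
            if not fathers:
                continue
            for mother in sorted(mothers, key=lambda x: x.id):
                for _ in range(config.offspring_per_female):
                    father = fathers[rng.integers(len(fathers))]
                    sex = "F" if rng.random() < 0.5 else "M"
                    child = Individual(id=new_id(), sex=sex, birth_group=g,
                                       mother_id=mother.id, father_id=father.id,
                                       birth_time=t_breed, generation=gen,
                                       current_group=g, entry_time=t_breed)
                    add_individual(child, mendelian_child(mother.id, father.id))

    study_end = config.n_generations * GENERATION_INTERVAL + 48.0

    # reveal a fraction of true statuses
    for iid in sorted(individuals):
        if rng.random() < config.status_known_prob:
            individuals[iid].known_status = individuals[iid].true_status

    # genotype table with missingness applied last
    ids = sorted(individuals)
    calls = np.stack([genotype_of[i] for i in ids])
    drop = rng.random((len(ids), config.n_loci)) < config.genotype_missing_rate
    calls[drop] = MISSING
    genotypes = GenotypeTable(ids, loci, calls)

    membership = pd.DataFrame(
        [(s[0], s[1], s[2], "" if s[3] is None else s[3]) for s in stints],
        columns=["individual", "group", "start", "end"])

    return Population(config=config, individuals=individuals, genotypes=genotypes,
                      membership=membership, allele_frequencies_true=true_freqs,
                      groups=groups, study_end=study_end)


def _matriline_root(individuals: Mapping[str, Individual], iid: str) -> str:
    ind = individuals[iid]
    while ind.mother_id is not None:
        ind = individuals[ind.mother_id]
    return ind.id


# -- scan sampling ----------------------------------------------------------


@dataclass
class ScanDataset:
    """Scan samples: per record the focal, its within-1 m neighbors, and
    whether every neighbor could be identified."""

    records: pd.DataFrame  # columns: focal_id, scan_id, neighbors (';'-joined), all_identified

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ScanDataset":
        df = pd.read_csv(path, keep_default_na=False)
        df["all_identified"] = df["all_identified"].astype(int)
        return cls(df)


def simulate_scans(population: Population | Mapping[str, Sequence[str]],
                   n_scans_per_individual: int = 46,
                   assortment_effect: float = 0.0,
                   base_rate: float = 0.03,
                   class_effects: Mapping[str, float] | None = None,
                   affinity: Mapping[frozenset, float] | None = None,
                   unidentified_rate: float = 0.0,
                   sexes: Mapping[str, str] | None = None,
                   seed: int | None = None) -> ScanDataset:
    """Simulate instantaneous scan samples of within-1 m neighbors.

    Each focal receives exactly ``n_scans_per_individual`` scans.  In each
    scan every co-group member is within one meter independently with a
    dyad-specific probability: ``base_rate`` plus the class effect
    (``assortment_effect`` adds to female-female dyads; ``class_effects``
    overrides per class), or the value from ``affinity`` when that dyad is
    listed.  With all effects zero every within-group dyad class has the
    same expected co-occurrence probability (an exchangeable null).
    """
    if assortment_effect < 0:
        raise ValueError("assortment_effect must be >= 0")
    if isinstance(population, Population):
        group_members = {g: population.members_of(g) for g in population.groups}
        sexes = population.sexes()
    else:
        group_members = {g: sorted(m) for g, m in population.items()}
        if sexes is None:
            raise ValueError("sexes mapping required when passing raw group membership")
    effects = {"FF": assortment_effect, "MM": 0.0, "MF": 0.0}
    if class_effects:
        effects.update(class_effects)
    rng = np.random.default_rng(seed)
    rows = []
    scan_counter = 0
    for g in sorted(group_members):
        members = group_members[g]
        if not members:
            raise ValueError(f"group {g!r} is empty")
        for focal in members:
            others = [m for m in members if m != focal]
            probs = np.empty(len(others))
            for k, other in enumerate(others):
                if affinity is not None and frozenset((focal, other)) in affinity:
                    probs[k] = affinity[frozenset((focal, other))]
                else:
                    cls = "".join(sorted(sexes[focal] + sexes[other]))
                    cls = {"FF": "FF", "MM": "MM", "FM": "MF"}[cls]
                    probs[k] = min(1.0, base_rate + effects[cls])
            hits = rng.random((n_scans_per_individual, len(others))) < probs
            flags = rng.random(n_scans_per_individual) >= unidentified_rate
            for s in range(n_scans_per_individual):
                scan_counter += 1
                neigh = ";".join(np.array(others)[hits[s]]) if len(others) else ""
                rows.append((focal, scan_counter, neigh, int(flags[s])))
    return ScanDataset(pd.DataFrame(
        rows, columns=["focal_id", "scan_id", "neighbors", "all_identified"]))


# -- tenure records ---------------------------------------------------------


def simulate_tenures(population: Population,
                     study_end: float | None = None) -> pd.DataFrame:
    """Build natal- and breeding-context tenure records from the membership
    history, right-censored at the end of the study window.

    Natal context: duration is the age at which the animal left its birth
    group (event observed) or its age at the study end (censored).  Breeding
    context: duration of each post-immigration residence spell.
    """
    end = population.study_end if study_end is None else study_end
    rows = []
    hist = population.membership
    for iid in sorted(population.individuals):
        ind = population.individuals[iid]
        if ind.birth_time >= end:
            continue
        spells = hist[hist["individual"] == iid].sort_values("start")
        first = spells.iloc[0]
        first_end = None if first["end"] == "" else float(first["end"])
        if first_end is not None and first_end <= end:
            rows.append((iid, ind.sex, "natal_group", first_end - ind.birth_time, True))
        else:
            rows.append((iid, ind.sex, "natal_group", end - ind.birth_time, False))
        for _, sp in spells.iloc[1:].iterrows():
            start = float(sp["start"])
            if start >= end:
                continue
            sp_end = None if sp["end"] == "" else float(sp["end"])
            if sp_end is not None and sp_end <= end:
                rows.append((iid, ind.sex, "breeding_group", sp_end - start, True))
            else:
                rows.append((iid, ind.sex, "breeding_group", end - start, False))
    df = pd.DataFrame(rows, columns=["individual", "sex", "context",
                                     "duration", "event_observed"])
    return df[df["duration"] > 0].reset_index(drop=True)
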
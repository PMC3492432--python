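"""End-to-end orchestration: simulate -> relatedness -> network ->
proximity -> resampling -> demography -> report.

A run is driven by a single ``RunConfig`` (loadable from YAML) and a master
seed.  Every stochastic stage receives a sub-seed derived deterministically
from the master seed, and all seeds, parameters, and output-file digests
are recorded in a JSON manifest, so a rerun with the same config and seed
reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import demography, network, proximity, relatedness, resampling, synthetic

__all__ = ["RunConfig", "run_pipeline", "summarize_groups", "combined_status"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    population: synthetic.PopulationConfig = field(
        default_factory=synthetic.PopulationConfig)
    # stage toggles
    run_genetics: bool = True
    run_proximity: bool = True
    run_demography: bool = True
    # relatedness / threshold
    estimator: str = "queller_goodnight"
    min_shared_loci: int = 10
    min_loci_typed: int = 10
    threshold_source: str = "fixed"          # or "calibrated"
    threshold_value: float = 0.43            # used when fixed
    n_known_kin: int = 55
    n_known_nonkin: int = 45
    # scans / proximity
    n_scans_per_individual: int = 46
    scan_base_rate: float = 0.03
    scan_assortment_effect: float = 0.02
    scan_unidentified_rate: float = 0.01
    min_scans: int = 10
    # resampling
    iterations: int = 10_000
    adults_only: bool = False
    # group-summary cutoffs on the proportion of natal adult females
    philopatric_cutoff: float = 2 / 3
    dispersed_cutoff: float = 1 / 3

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        pop = synthetic.PopulationConfig(**raw.pop("population", {}))
        return cls(population=pop, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _known_dyad_sets(population: synthetic.Population,
                     rmat: relatedness.RelatednessMatrix,
                     n_kin: int, n_nonkin: int, rng) -> tuple[list, list, pd.DataFrame]:
    """Draw calibration dyads: known close kin (parent-offspring and full
    sibs) and known non-kin (no shared ancestor), restricted to dyads that
    carry an R estimate."""
    ped = population.pedigree_dyads()
    kin = [(a, b, rel) for a, b, rel in ped.itertuples(index=False)
           if rmat.value(a, b) is not None]
    if len(kin) > n_kin:
        idx = sorted(rng.choice(len(kin), size=n_kin, replace=False))
        kin = [kin[k] for k in idx]
    ancestors: dict[str, frozenset] = {}

    def anc(iid: str) -> frozenset:
        if iid not in ancestors:
            ind = population.individuals[iid]
            out = {iid}
            for parent in (ind.mother_id, ind.father_id):
                if parent is not None:
                    out |= anc(parent)
            ancestors[iid] = frozenset(out)
        return ancestors[iid]

    ids = sorted(population.individuals)
    nonkin = []
    tries = 0
    while len(nonkin) < n_nonkin and tries < 50 * n_nonkin:
        tries += 1
        a, b = (ids[k] for k in rng.choice(len(ids), size=2, replace=False))
        if a > b:
            a, b = b, a
        if anc(a) & anc(b):
            continue
        if rmat.value(a, b) is None or (a, b) in {(x, y) for x, y, _ in nonkin}:
            continue
        nonkin.append((a, b, "non_kin"))
    known = pd.DataFrame(kin + nonkin, columns=["id1", "id2", "relation"])
    kin_R = [rmat.value(a, b) for a, b, _ in kin]
    nonkin_R = [rmat.value(a, b) for a, b, _ in nonkin]
    return kin_R, nonkin_R, known


def combined_status(known_status: Mapping[str, str],
                    assignments: Mapping[str, network.StatusAssignment]) -> dict[str, str]:
    """Merge demographic (known) and network-inferred (likely) status into
    one natal/immigrant/unknown label per individual."""
    out: dict[str, str] = {}
    for iid, st in known_status.items():
        if st in ("natal", "immigrant"):
            out[iid] = st
    for iid, asg in assignments.items():
        if iid in out:
            continue
        if asg.assigned == network.LIKELY_NATAL:
            out[iid] = "natal"
        elif asg.assigned == network.LIKELY_IMMIGRANT:
            out[iid] = "immigrant"
        else:
            out[iid] = "unknown"
    return out


def summarize_groups(status: Mapping[str, str],
                     sexes: Mapping[str, str],
                     age_classes: Mapping[str, str],
                     groups: Mapping[str, str],
                     r_nulls: Sequence[resampling.NullResult] = (),
                     prox_nulls: Sequence[resampling.NullResult] = (),
                     philopatric_cutoff: float = 2 / 3,
                     dispersed_cutoff: float = 1 / 3) -> pd.DataFrame:
    """Per-group summary: dispersal-pattern label, kin-based and bonded
    flags (95%-level significance of the female-female within-group
    nulls), and the observed female-female means.

    The dispersal label follows the proportion of adult females with a
    natal (known or likely) status: philopatric at or above
    ``philopatric_cutoff``, dispersed at or below ``dispersed_cutoff``,
    facultative in between.
    """
    r_ff = {r.group: r for r in r_nulls if r.dyad_class == "FF"}
    p_ff = {r.group: r for r in prox_nulls if r.dyad_class == "FF"}
    rows = []
    for g in sorted(set(groups.values())):
        females = [i for i, grp in groups.items()
                   if grp == g and sexes.get(i) == "F"
                   and age_classes.get(i) == "adult"]
        classified = [i for i in females if status.get(i) in ("natal", "immigrant")]
        if classified:
            prop_natal = sum(status[i] == "natal" for i in classified) / len(classified)
            if prop_natal >= philopatric_cutoff:
                label = "philopatric"
            elif prop_natal <= dispersed_cutoff:
                label = "dispersed"
            else:
                label = "facultative"
        else:
            prop_natal, label = float("nan"), "unknown"

        def flag(res):
            if res is None:
                return ""
            return "yes" if res.direction95 == "above" else "no"

        rows.append({
            "group": g, "n_adult_females": len(females),
            "prop_natal_females": prop_natal, "dispersal_pattern": label,
            "kin_based": flag(r_ff.get(g)),
            "mean_ff_R": r_ff[g].observed_mean if g in r_ff else float("nan"),
            "bonded": flag(p_ff.get(g)),
            "mean_ff_proximity": p_ff[g].observed_mean if g in p_ff else float("nan"),
        })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, out_dir, seed: int = 0) -> dict:
    """Run all enabled stages into ``out_dir`` and return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(seed)
    stage_seeds = {name: int(s.generate_state(1)[0] % (2**31 - 1))
                   for name, s in zip(
                       ("simulate", "calibrate", "scans", "resample_prox",
                        "resample_r", "population_null"),
                       master.spawn(6))}
    manifest: dict = {"seed": seed, "stage_seeds": stage_seeds,
                      "config": config.to_dict(), "outputs": {}}

    # -- simulate -----------------------------------------------------------
    pop_cfg = dataclasses.replace(config.population, seed=stage_seeds["simulate"])
    population = synthetic.simulate_population(pop_cfg)
    population.genotypes.to_csv(out / "genotypes.csv")
    population.demography_frame().to_csv(out / "demography.csv", index=False)
    population.membership.to_csv(out / "membership.csv", index=False)

    groups = population.current_groups()
    sexes = population.sexes()
    ages = population.age_classes()
    known_status = {i: ind.known_status for i, ind in population.individuals.items()}
    true_status = {i: ind.true_status for i, ind in population.individuals.items()}

    prox_nulls: list[resampling.NullResult] = []
    r_nulls: list[resampling.NullResult] = []
    assignments: dict[str, network.StatusAssignment] = {}

    # -- genetics -----------------------------------------------------------
    if config.run_genetics:
        freqs = relatedness.estimate_allele_frequencies(population.genotypes)
        rmat = relatedness.estimate_relatedness(
            population.genotypes, freqs, estimator=config.estimator,
            min_shared_loci=config.min_shared_loci)
        rmat.to_csv(out / "relatedness.csv")

        rng = np.random.default_rng(stage_seeds["calibrate"])
        kin_R, nonkin_R, known_dyads = _known_dyad_sets(
            population, rmat, config.n_known_kin, config.n_known_nonkin, rng)
        known_dyads.to_csv(out / "known_dyads.csv", index=False)
        calibrated = relatedness.calibrate_threshold(kin_R, nonkin_R)
        manifest["calibration"] = dataclasses.asdict(calibrated)
        if config.threshold_source == "calibrated":
            threshold = calibrated
        else:
            threshold = relatedness.fixed_threshold(config.threshold_value)
        manifest["threshold"] = dataclasses.asdict(threshold)

        ties = relatedness.classify_genetic_ties(rmat, threshold)
        ties.to_csv(out / "ties.csv")

        annotations = {i: {"sex": sexes[i], "known_status": known_status[i],
                           "n_loci_typed": rmat.n_loci_typed.get(i, 0),
                           "generation": population.individuals[i].generation}
                       for i in groups}
        graph = network.build_network(ties, groups, annotations)
        clusters = network.find_clusters(graph)
        pd.DataFrame(sorted(clusters.items()), columns=["id", "cluster"]) \
            .to_csv(out / "clusters.csv", index=False)

        offspring = population.offspring_map()
        assignments = network.assign_dispersal_status(
            graph, known_status, offspring, min_loci_typed=config.min_loci_typed)
        eval_assignments = network.assign_dispersal_status(
            graph, known_status, offspring, min_loci_typed=config.min_loci_typed,
            reassign_known=True)
        _assignments_csv(eval_assignments, out / "assignments.csv")
        confusion = network.evaluate_assignments(eval_assignments, known_status)
        confusion.to_frame().to_csv(out / "confusion.csv", index=False)
        with_ties = network.evaluate_assignments(eval_assignments, known_status,
                                                 require_tie=True)
        manifest["classifier"] = {
            "n_evaluated": confusion.n,
            "correct_pct": confusion.correct_pct,
            "incorrect_pct": confusion.incorrect_pct,
            "unassigned_pct": confusion.unassigned_pct,
            "correct_pct_with_ties": with_ties.correct_pct,
            "n_with_ties": with_ties.n,
        }

        # within-group relatedness nulls + population-level null
        r_long = rmat.dyads().rename(columns={"R": "value"})
        r_mat = resampling.DyadicMatrix.from_long(r_long, sexes, groups=groups)
        if config.adults_only:
            adults = {i for i, a in ages.items() if a == "adult"}
            r_mat = resampling.DyadicMatrix(
                r_mat.table[r_mat.table["id1"].isin(adults)
                            & r_mat.table["id2"].isin(adults)])
        r_nulls = resampling.within_group_nulls(
            r_mat, iterations=config.iterations, seed=stage_seeds["resample_r"])
        resampling.summarize_significance(r_nulls) \
            .to_csv(out / "relatedness_nulls.csv", index=False, float_format="%.10g")
        pop_rows = []
        for sex in ("F", "M"):
            try:
                res = resampling.population_null(
                    rmat, groups, sexes, sex, iterations=config.iterations,
                    seed=stage_seeds["population_null"])
            except ValueError:
                continue
            pop_rows.append({
                "sex": sex, "observed_grand_mean": res.observed_grand_mean,
                "ci95_lower": res.ci95[0], "ci95_upper": res.ci95[1],
                "ci99_lower": res.ci99[0], "ci99_upper": res.ci99[1],
                "direction95": res.direction95, "direction99": res.direction99,
            })
        pd.DataFrame(pop_rows).to_csv(out / "population_nulls.csv",
                                      index=False, float_format="%.10g")

    # -- proximity ----------------------------------------------------------
    if config.run_proximity:
        scans = synthetic.simulate_scans(
            population, n_scans_per_individual=config.n_scans_per_individual,
            assortment_effect=config.scan_assortment_effect,
            base_rate=config.scan_base_rate,
            unidentified_rate=config.scan_unidentified_rate,
            seed=stage_seeds["scans"])
        scans.to_csv(out / "scans.csv")
        prox = proximity.compute_proximity(scans, groups,
                                           min_scans=config.min_scans)
        prox.to_csv(out / "proximity.csv")
        p_long = prox.scores.rename(columns={"score": "value"})
        p_mat = resampling.DyadicMatrix.from_long(p_long, sexes)
        if config.adults_only:
            adults = {i for i, a in ages.items() if a == "adult"}
            p_mat = resampling.DyadicMatrix(
                p_mat.table[p_mat.table["id1"].isin(adults)
                            & p_mat.table["id2"].isin(adults)])
        prox_nulls = resampling.within_group_nulls(
            p_mat, iterations=config.iterations, seed=stage_seeds["resample_prox"])
        resampling.summarize_significance(prox_nulls) \
            .to_csv(out / "proximity_nulls.csv", index=False, float_format="%.10g")

    # -- demography ---------------------------------------------------------
    if config.run_demography:
        tenures = synthetic.simulate_tenures(population)
        tenures.to_csv(out / "tenures.csv", index=False, float_format="%.10g")
        surv_rows = []
        for context in ("natal_group", "breeding_group"):
            for sex in ("M", "F"):
                try:
                    curve = demography.kaplan_meier(tenures, context=context, sex=sex)
                except ValueError:
                    continue
                frame = curve.to_frame()
                frame.insert(0, "sex", sex)
                frame.insert(0, "context", context)
                surv_rows.append(frame)
                manifest.setdefault("survival", {})[f"{context}_{sex}"] = {
                    "median": curve.median, "n": curve.n}
        if surv_rows:
            pd.concat(surv_rows).to_csv(out / "survival.csv", index=False,
                                        float_format="%.10g")
        test_rows = []
        for context in ("natal_group", "breeding_group"):
            try:
                lr = demography.logrank_test(tenures, context=context)
                test_rows.append({"test": f"logrank_{context}",
                                  "statistic": lr.statistic, "df": lr.df, "p": lr.p})
            except ValueError:
                pass
        events = _dispersal_event_counts(population)
        n_m = sum(1 for s in sexes.values() if s == "M")
        n_f = sum(1 for s in sexes.values() if s == "F")
        for kind in ("immigration", "emigration"):
            for method in ("chi_square_yates", "fisher_exact"):
                try:
                    res = demography.sex_bias_count_test(
                        events[kind]["M"], events[kind]["F"], n_m, n_f,
                        method=method)
                except ValueError:
                    continue
                test_rows.append({"test": f"{kind}_{method}",
                                  "statistic": res.statistic, "df": res.df,
                                  "p": res.p})
        pd.DataFrame(test_rows).to_csv(out / "tests.csv", index=False,
                                       float_format="%.10g")

    # -- report -------------------------------------------------------------
    status = combined_status(known_status, assignments)
    summary = summarize_groups(status, sexes, ages, groups,
                               r_nulls=r_nulls, prox_nulls=prox_nulls,
                               philopatric_cutoff=config.philopatric_cutoff,
                               dispersed_cutoff=config.dispersed_cutoff)
    summary.to_csv(out / "group_summary.csv", index=False, float_format="%.10g")

    for path in sorted(out.glob("*.csv")):
        manifest["outputs"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _assignments_csv(assignments: Mapping[str, network.StatusAssignment],
                     path) -> None:
    rows = []
    for iid in sorted(assignments):
        a = assignments[iid]
        counts = ";".join(f"{g}:{c}" for g, c in sorted(a.counts.items()))
        rows.append({"id": iid, "assigned": a.assigned, "basis": a.basis,
                     "counts": counts})
    pd.DataFrame(rows).to_csv(path, index=False)


def _dispersal_event_counts(population: synthetic.Population) -> dict:
    """Immigration and emigration events per sex over the study window,
    read off the membership history (each closed residence spell is an
    emigration; each non-first spell start is an immigration)."""
    counts = {"immigration": {"M": 0, "F": 0}, "emigration": {"M": 0, "F": 0}}
    hist = population.membership
    for iid, spells in hist.groupby("individual"):
        sex = population.individuals[iid].sex
        spells = spells.sort_values("start")
        closed = (spells["end"] != "").sum()
        counts["emigration"][sex] += int(closed)
        counts["immigration"][sex] += max(len(spells) - 1, 0)
    return counts
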
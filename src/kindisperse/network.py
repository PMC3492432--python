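"""Genetic-tie networks and dispersal-status inference.

Individuals are nodes; dyads whose relatedness exceeds the close-kin
threshold are edges.  Connected components of the tie graph are "genetic
clusters".  Dispersal status is inferred from where an animal's close kin
live: an animal with fewer close kin in its current group than in some
other group is a likely immigrant, one with strictly more is likely natal,
and ties between groups are broken by the (known or already-inferred)
status of the tied kin, iterated to a fixed point.  Co-residing offspring
are not counted toward the current group, because a parent may have
immigrated before the offspring was born.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .relatedness import TieSet

__all__ = [
    "build_network",
    "find_clusters",
    "StatusAssignment",
    "assign_dispersal_status",
    "ConfusionSummary",
    "evaluate_assignments",
]

LIKELY_NATAL = "likely_natal"
LIKELY_IMMIGRANT = "likely_immigrant"
UNKNOWN = "unknown"


def build_network(ties: TieSet | pd.DataFrame,
                  groups: Mapping[str, str],
                  annotations: Mapping[str, Mapping] | None = None,
                  adults_only: bool = False,
                  age_classes: Mapping[str, str] | None = None) -> nx.Graph:
    """Build the undirected genetic-tie graph.

    Every individual in ``groups`` becomes a node (isolates included),
    annotated with its group plus any extra ``annotations`` (sex,
    known_status, n_loci_typed, generation...).  ``adults_only`` drops
    non-adult nodes (requires ``age_classes``), the filter used for the
    adults-only display of the network.
    """
    edges = ties.edges if isinstance(ties, TieSet) else ties
    graph = nx.Graph()
    for node, group in groups.items():
        attrs = dict(annotations.get(node, {})) if annotations else {}
        graph.add_node(node, group=group, **attrs)
    for rec in edges.itertuples(index=False):
        if rec.id1 not in graph or rec.id2 not in graph:
            raise ValueError(f"tie references unknown individual: {rec.id1}-{rec.id2}")
        graph.add_edge(rec.id1, rec.id2, R=float(rec.R))
    if adults_only:
        if age_classes is None:
            raise ValueError("adults_only requires age_classes")
        drop = [n for n in graph if age_classes.get(n) != "adult"]
        graph.remove_nodes_from(drop)
    return graph


def find_clusters(network: nx.Graph) -> dict[str, int]:
    """Label genetic clusters (connected components of the tie graph).

    Nodes without ties each form their own singleton cluster.  Labels are
    assigned deterministically by the smallest member id of each component.
    """
    comps = sorted(nx.connected_components(network), key=lambda c: min(c))
    return {node: k for k, comp in enumerate(comps) for node in comp}


@dataclass
class StatusAssignment:
    """Inferred dispersal status for one individual.

    ``basis`` records how the call was made: a strict majority of close-kin
    counts, the status-based tie rule, the absence of close kin, or an
    unresolvable tie.
    """

    id: str
    assigned: str                 # likely_natal | likely_immigrant | unknown
    basis: str                    # count_majority | tie_rule | no_close_kin | unresolved
    counts: dict[str, int] = field(default_factory=dict)  # close kin per group


def _kin_counts(graph: nx.Graph, focal: str, groups: Mapping[str, str],
                offspring: set[str]) -> tuple[dict[str, int], dict[str, list[str]]]:
    """Close kin of ``focal`` per group, excluding co-residing offspring
    from the current-group count."""
    home = groups[focal]
    counts: dict[str, int] = {}
    members: dict[str, list[str]] = {}
    for kin in graph.neighbors(focal):
        g = groups[kin]
        if g == home and kin in offspring:
            continue
        counts[g] = counts.get(g, 0) + 1
        members.setdefault(g, []).append(kin)
    return counts, members


def assign_dispersal_status(network: nx.Graph,
                            known_status: Mapping[str, str],
                            offspring_map: Mapping[str, Iterable[str]],
                            min_loci_typed: int = 10,
                            n_loci_typed: Mapping[str, int] | None = None,
                            reassign_known: bool = False,
                            order: Iterable[str] | None = None) -> dict[str, StatusAssignment]:
    """Infer likely dispersal status from the distribution of close kin.

    Individuals passing the per-individual loci filter are processed (with
    ``reassign_known`` False, only those lacking a known status; with True,
    known-status animals are also run through the classifier — ignoring
    their own known status — which is how the method's accuracy is scored
    against the demographic record).  The status-based tie rules are swept
    to a fixed point; the result is independent of sweep order because
    assignments, once made, are never revised.
    """
    groups = nx.get_node_attributes(network, "group")
    if n_loci_typed is None:
        n_loci_typed = nx.get_node_attributes(network, "n_loci_typed")

    def passes_filter(node: str) -> bool:
        if not n_loci_typed:
            return True
        return n_loci_typed.get(node, 0) >= min_loci_typed

    known = {i: s for i, s in known_status.items()
             if s in ("natal", "immigrant") and i in network}
    targets = sorted(n for n in network
                     if passes_filter(n) and (reassign_known or n not in known))
    if order is not None:
        order = [n for n in order if n in set(targets)]
    else:
        order = targets

    out: dict[str, StatusAssignment] = {}
    resolved: dict[str, str] = dict(known)  # id -> "natal"|"immigrant"

    def kin_status(kin: str, focal: str) -> str | None:
        # a focal's own known status never feeds its own classification
        if kin == focal:
            return None
        return resolved.get(kin)

    # pass 0: counts and count-majority calls (status-independent)
    pending: list[str] = []
    for focal in order:
        offspring = set(offspring_map.get(focal, ()))
        counts, members = _kin_counts(network, focal, groups, offspring)
        home = groups[focal]
        cur = counts.get(home, 0)
        others = {g: c for g, c in counts.items() if g != home}
        if sum(counts.values()) == 0:
            out[focal] = StatusAssignment(focal, UNKNOWN, "no_close_kin", counts)
        elif others and cur < max(others.values()):
            out[focal] = StatusAssignment(focal, LIKELY_IMMIGRANT, "count_majority", counts)
        elif not others or cur > max(others.values()):
            out[focal] = StatusAssignment(focal, LIKELY_NATAL, "count_majority", counts)
        else:
            pending.append(focal)
        if focal in out and focal not in known:
            label = out[focal].assigned
            if label in (LIKELY_NATAL, LIKELY_IMMIGRANT):
                resolved[focal] = "natal" if label == LIKELY_NATAL else "immigrant"

    # tie rules, iterated to a fixed point
    changed = True
    sweeps = 0
    while changed and sweeps <= len(pending) + 1:
        changed = False
        sweeps += 1
        for focal in list(pending):
            offspring = set(offspring_map.get(focal, ()))
            counts, members = _kin_counts(network, focal, groups, offspring)
            home = groups[focal]
            cur = counts.get(home, 0)
            tied = [g for g, c in counts.items() if g != home and c == cur]
            home_status = [kin_status(k, focal) for k in members.get(home, [])]
            away_status = [kin_status(k, focal)
                           for g in tied for k in members.get(g, [])]
            if None in home_status or None in away_status:
                continue  # wait for kin to resolve
            label = None
            if all(s == "natal" for s in home_status) and \
                    all(s == "immigrant" for s in away_status):
                label = LIKELY_NATAL
            elif all(s == "immigrant" for s in home_status) and \
                    all(s == "natal" for s in away_status):
                label = LIKELY_IMMIGRANT
            if label is None:
                continue
            out[focal] = StatusAssignment(focal, label, "tie_rule", counts)
            if focal not in known:
                resolved[focal] = "natal" if label == LIKELY_NATAL else "immigrant"
            pending.remove(focal)
            changed = True

    for focal in pending:
        offspring = set(offspring_map.get(focal, ()))
        counts, _ = _kin_counts(network, focal, groups, offspring)
        out[focal] = StatusAssignment(focal, UNKNOWN, "unresolved", counts)
    return out


@dataclass
class ConfusionSummary:
    """Known-status vs assigned-status cross-tabulation.

    Percentages are over the individuals with known status included in the
    evaluation; correct + incorrect + unassigned = 100 (within rounding).
    """

    cells: dict[tuple[str, str], int]
    n: int
    correct_pct: float
    incorrect_pct: float
    unassigned_pct: float

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, a, c) for (k, a), c in sorted(self.cells.items())]
        return pd.DataFrame(rows, columns=["known", "assigned", "count"])


_MATCH = {("natal", LIKELY_NATAL), ("immigrant", LIKELY_IMMIGRANT)}


def evaluate_assignments(assignments: Mapping[str, StatusAssignment],
                         known_status: Mapping[str, str],
                         require_tie: bool = False) -> ConfusionSummary:
    """Score inferred status against known status.

    ``require_tie`` restricts the evaluation to individuals with at least
    one genetic tie (those whose classification could possibly succeed).
    """
    cells: dict[tuple[str, str], int] = {}
    n = correct = incorrect = 0
    for iid, status in known_status.items():
        if status not in ("natal", "immigrant") or iid not in assignments:
            continue
        asg = assignments[iid]
        if require_tie and sum(asg.counts.values()) == 0 and asg.basis == "no_close_kin":
            continue
        n += 1
        cells[(status, asg.assigned)] = cells.get((status, asg.assigned), 0) + 1
        if (status, asg.assigned) in _MATCH:
            correct += 1
        elif asg.assigned != UNKNOWN:
            incorrect += 1
    if n == 0:
        raise ValueError("no individuals with known status to evaluate")
    return ConfusionSummary(
        cells=cells, n=n,
        correct_pct=100.0 * correct / n,
        incorrect_pct=100.0 * incorrect / n,
        unassigned_pct=100.0 * (n - correct - incorrect) / n,
    )
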
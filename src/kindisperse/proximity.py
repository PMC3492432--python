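"""Dyadic proximity scores from instantaneous scan samples.

The proximity score of animals A and B is the mean of two directed
proportions: the proportion of A's scans in which B was within one meter,
and the proportion of B's scans in which A was within one meter.  Scans in
which not every neighbor could be identified are dropped before counting,
and individuals with too few retained scans are excluded.  Scores are
computed only for dyads resident in the same group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .synthetic import ScanDataset

__all__ = ["ProximityMatrix", "compute_proximity"]


@dataclass
class ProximityMatrix:
    """Within-group dyadic proximity scores in [0, 1].

    ``scores`` holds one row per unordered dyad (id1 < id2) with the two
    directed proportions and their mean; ``n_scans_used`` is the per-focal
    retained scan count.
    """

    scores: pd.DataFrame     # id1, id2, group, p_12, p_21, score
    n_scans_used: dict[str, int]
    min_scans: int

    def value(self, a: str, b: str) -> float | None:
        x, y = sorted((a, b))
        hit = self.scores[(self.scores["id1"] == x) & (self.scores["id2"] == y)]
        return None if hit.empty else float(hit["score"].iloc[0])

    def to_csv(self, path) -> None:
        self.scores.to_csv(path, index=False, float_format="%.10g")


def compute_proximity(scans: ScanDataset,
                      groups: Mapping[str, str],
                      min_scans: int = 10,
                      drop_unidentified: bool = True) -> ProximityMatrix:
    """Compute proximity scores for all co-resident dyads.

    ``groups`` maps individual id to its group for the analysis window.
    Individuals with fewer than ``min_scans`` retained scans carry no
    scores; a dyad needs both members retained.
    """
    if min_scans < 1:
        raise ValueError("min_scans must be >= 1")
    df = scans.records
    if drop_unidentified:
        df = df[df["all_identified"].astype(int) == 1]

    neighbor_sets: dict[str, list[set[str]]] = {}
    for rec in df.itertuples(index=False):
        raw = rec.neighbors
        neigh = set() if (pd.isna(raw) or raw == "") else set(str(raw).split(";"))
        if rec.focal_id in neigh:
            raise ValueError(f"focal {rec.focal_id} appears in its own neighbor set")
        neighbor_sets.setdefault(rec.focal_id, []).append(neigh)

    n_scans = {i: len(s) for i, s in neighbor_sets.items()}
    retained = sorted(i for i, c in n_scans.items()
                      if c >= min_scans and i in groups)

    rows = []
    for k, a in enumerate(retained):
        for b in retained[k + 1:]:
            if groups[a] != groups[b]:
                continue
            p_ab = sum(b in s for s in neighbor_sets[a]) / n_scans[a]
            p_ba = sum(a in s for s in neighbor_sets[b]) / n_scans[b]
            rows.append((a, b, groups[a], p_ab, p_ba, 0.5 * (p_ab + p_ba)))
    scores = pd.DataFrame(rows, columns=["id1", "id2", "group",
                                         "p_12", "p_21", "score"])
    return ProximityMatrix(scores=scores,
                           n_scans_used={i: n_scans[i] for i in retained},
                           min_scans=min_scans)
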
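"""Pairwise relatedness from STR genotypes and close-kin threshold calling.

Dyadic relatedness R is estimated with published moment estimators
(Queller & Goodnight's regression estimator by default, Lynch & Ritland's
as an alternative), using reference allele frequencies estimated from the
whole sample.  A close-kin threshold is calibrated as the lowest R observed
among known parent-offspring and full-sibling dyads; dyads whose R lies
strictly above the threshold form "genetic ties", the edges of the kin
network used downstream for dispersal-status inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic import MISSING, GenotypeTable

__all__ = [
    "AlleleFrequencies",
    "RelatednessMatrix",
    "KinThreshold",
    "TieSet",
    "estimate_allele_frequencies",
    "estimate_relatedness",
    "calibrate_threshold",
    "fixed_threshold",
    "classify_genetic_ties",
]

ESTIMATORS = ("queller_goodnight", "lynch_ritland")
_ALIASES = {"qg": "queller_goodnight", "lr": "lynch_ritland"}


@dataclass
class AlleleFrequencies:
    """Per-locus allele frequency tables (each summing to one)."""

    freqs: dict[str, dict[int, float]]
    excluded_loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for locus, table in self.freqs.items():
            total = sum(table.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {locus} sum to {total}, not 1")
            if any(p < 0 for p in table.values()):
                raise ValueError(f"negative frequency at {locus}")

    def lookup(self, loci: Sequence[str], max_allele: int) -> np.ndarray:
        """Dense (n_loci, max_allele+1) frequency lookup, label-indexed."""
        table = np.zeros((len(loci), max_allele + 1))
        for j, locus in enumerate(loci):
            for allele, p in self.freqs[locus].items():
                table[j, allele] = p
        return table


def estimate_allele_frequencies(genotypes: GenotypeTable) -> AlleleFrequencies:
    """Allele frequencies by direct counting over non-missing calls.

    Loci without a single non-missing call are excluded and recorded in
    ``excluded_loci``.
    """
    freqs: dict[str, dict[int, float]] = {}
    excluded: list[str] = []
    for j, locus in enumerate(genotypes.loci):
        calls = genotypes.calls[:, j, :].ravel()
        calls = calls[calls != MISSING]
        if calls.size == 0:
            excluded.append(locus)
            continue
        labels, counts = np.unique(calls, return_counts=True)
        freqs[locus] = {int(a): c / calls.size for a, c in zip(labels, counts)}
    return AlleleFrequencies(freqs, excluded)


class RelatednessMatrix:
    """Symmetric dyadic R estimates with per-dyad locus counts.

    A dyad carries an estimate only when the two members are both typed at
    at least ``min_shared_loci`` loci (otherwise ``value`` returns None).
    """

    def __init__(self, ids: Sequence[str], r: np.ndarray, n_shared: np.ndarray,
                 n_loci_typed: Mapping[str, int], min_shared_loci: int,
                 estimator: str):
        self.ids = list(ids)
        self._row = {i: k for k, i in enumerate(self.ids)}
        self.r = r                      # (n, n), NaN where no estimate
        self.n_shared = n_shared        # (n, n) ints
        self.n_loci_typed = dict(n_loci_typed)
        self.min_shared_loci = min_shared_loci
        self.estimator = estimator

    def value(self, a: str, b: str) -> float | None:
        v = self.r[self._row[a], self._row[b]]
        return None if np.isnan(v) else float(v)

    def n_loci(self, a: str, b: str) -> int:
        return int(self.n_shared[self._row[a], self._row[b]])

    def dyads(self) -> pd.DataFrame:
        """Long-format table of evaluable dyads (id1 < id2)."""
        rows = []
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                if not np.isnan(self.r[i, j]):
                    rows.append((self.ids[i], self.ids[j],
                                 float(self.r[i, j]), int(self.n_shared[i, j])))
        return pd.DataFrame(rows, columns=["id1", "id2", "R", "n_loci"])

    def to_csv(self, path) -> None:
        self.dyads().to_csv(path, index=False, float_format="%.10g")

    def submatrix_mean(self, members: Sequence[str]) -> float:
        """Mean R over evaluable dyads among ``members`` (NaN if none)."""
        rows = [self._row[m] for m in members]
        sub = self.r[np.ix_(rows, rows)]
        iu = np.triu_indices(len(rows), k=1)
        vals = sub[iu]
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if vals.size else float("nan")


def _prepare(genotypes: GenotypeTable, freqs: AlleleFrequencies):
    keep = [j for j, l in enumerate(genotypes.loci) if l in freqs.freqs]
    loci = [genotypes.loci[j] for j in keep]
    calls = genotypes.calls[:, keep, :]
    observed = calls[calls != MISSING]
    for j, locus in enumerate(loci):
        seen = set(np.unique(calls[:, j, :][calls[:, j, 0] != MISSING]))
        if not seen <= set(freqs.freqs[locus]):
            raise ValueError(f"alleles at {locus} missing from frequency table")
    max_in_freqs = max((a for l in loci for a in freqs.freqs[l]), default=0)
    max_allele = max(int(observed.max()) if observed.size else 0, max_in_freqs)
    p = freqs.lookup(loci, max_allele)  # (L, A+1)
    return calls, loci, p


def estimate_relatedness(genotypes: GenotypeTable, freqs: AlleleFrequencies,
                         estimator: str = "queller_goodnight",
                         min_shared_loci: int = 10) -> RelatednessMatrix:
    """Estimate R for every dyad typed together at >= ``min_shared_loci`` loci.

    Both estimators combine loci as ratios of summed locus-wise numerators
    and denominators (for Lynch-Ritland, the published information weights),
    and symmetrize over the two orderings of the dyad.
    """
    estimator = _ALIASES.get(estimator, estimator)
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")
    calls, loci, p = _prepare(genotypes, freqs)
    n = len(genotypes.ids)
    L = len(loci)
    typed = calls[:, :, 0] != MISSING  # (n, L)

    r = np.full((n, n), np.nan)
    n_shared = np.zeros((n, n), dtype=int)
    cols = np.arange(L)
    a1 = calls[:, :, 0]
    a2 = calls[:, :, 1]
    safe1 = np.where(a1 == MISSING, 0, a1)
    safe2 = np.where(a2 == MISSING, 0, a2)
    p1 = p[cols, safe1]   # (n, L) frequency of first allele
    p2 = p[cols, safe2]

    iu, ju = np.triu_indices(n, k=1)
    shared = typed[iu] & typed[ju]      # (npairs, L)
    n_shared[iu, ju] = n_shared[ju, iu] = shared.sum(axis=1)

    A1, A2, B1, B2 = a1[iu], a2[iu], a1[ju], a2[ju]
    Pa1, Pa2, Pb1, Pb2 = p1[iu], p2[iu], p1[ju], p2[ju]
    Sac = (A1 == B1).astype(float)
    Sad = (A1 == B2).astype(float)
    Sbc = (A2 == B1).astype(float)
    Sbd = (A2 == B2).astype(float)
    Sab = (A1 == A2).astype(float)
    Scd = (B1 == B2).astype(float)

    if estimator == "queller_goodnight":
        num_x = 0.5 * (Sac + Sad + Sbc + Sbd) - Pa1 - Pa2
        den_x = 1.0 + Sab - Pa1 - Pa2
        num_y = 0.5 * (Sac + Sad + Sbc + Sbd) - Pb1 - Pb2
        den_y = 1.0 + Scd - Pb1 - Pb2
        num = np.where(shared, num_x + num_y, 0.0).sum(axis=1)
        den = np.where(shared, den_x + den_y, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            est = np.where(den != 0, num / den, np.nan)
    else:  # lynch_ritland
        est = _lynch_ritland(shared, Sac, Sad, Sbc, Sbd, Sab, Scd,
                             Pa1, Pa2, Pb1, Pb2)

    ok = n_shared[iu, ju] >= min_shared_loci
    vals = np.where(ok, est, np.nan)
    r[iu, ju] = r[ju, iu] = vals
    return RelatednessMatrix(genotypes.ids, r, n_shared,
                             genotypes.n_loci_typed(), min_shared_loci, estimator)


def _lr_directed(shared, Sxy1, Sxy2, Syx1, Syx2, Sref_hom, pa, pb):
    """Lynch-Ritland regression of proband on reference (a,b)=reference
    alleles with frequencies pa, pb; S terms are the four sharing
    indicators.  Returns weighted per-pair estimate components."""
    num = pa * (Syx1 + Syx2) + pb * (Sxy1 + Sxy2) - 4.0 * pa * pb
    den = (1.0 + Sref_hom) * (pa + pb) - 4.0 * pa * pb
    with np.errstate(invalid="ignore", divide="ignore"):
        weight = den / (2.0 * pa * pb)
    usable = shared & (den > 1e-12) & np.isfinite(weight)
    wsum = np.where(usable, weight, 0.0).sum(axis=1)
    # weighted mean of r_l = num/den with weights w_l: sum(w*r) = sum(num/(2 pa pb))
    with np.errstate(invalid="ignore", divide="ignore"):
        wr = np.where(usable, num / (2.0 * pa * pb), 0.0).sum(axis=1)
        return np.where(wsum > 0, wr / wsum, np.nan)


def _lynch_ritland(shared, Sac, Sad, Sbc, Sbd, Sab, Scd, Pa1, Pa2, Pb1, Pb2):
    rx = _lr_directed(shared, Sac + Sad, 0 * Sac, Sbc + Sbd, 0 * Sac, Sab, Pa1, Pa2)
    ry = _lr_directed(shared, Sac + Sbc, 0 * Sac, Sad + Sbd, 0 * Sac, Scd, Pb1, Pb2)
    both = ~np.isnan(rx) & ~np.isnan(ry)
    out = np.where(both, 0.5 * (rx + ry), np.nan)
    only_x = ~np.isnan(rx) & np.isnan(ry)
    only_y = np.isnan(rx) & ~np.isnan(ry)
    out = np.where(only_x, rx, out)
    return np.where(only_y, ry, out)


@dataclass(frozen=True)
class KinThreshold:
    """Close-kin R threshold with its calibration provenance.

    ``overlap`` is True when the highest known non-kin R reaches the
    threshold, i.e. the calibration sets cannot be separated cleanly.
    """

    threshold: float
    source: str                      # "calibrated" | "fixed"
    known_kin_min: float
    known_nonkin_max: float
    overlap: bool


def calibrate_threshold(known_kin_R: Sequence[float],
                        known_nonkin_R: Sequence[float] = ()) -> KinThreshold:
    """Set the close-kin threshold to the lowest R among known
    parent-offspring / full-sibling dyads."""
    kin = [float(v) for v in known_kin_R]
    if not kin:
        raise ValueError("known_kin_R must be non-empty")
    threshold = min(kin)
    nonkin_max = max((float(v) for v in known_nonkin_R), default=float("-inf"))
    return KinThreshold(threshold=threshold, source="calibrated",
                        known_kin_min=threshold, known_nonkin_max=nonkin_max,
                        overlap=nonkin_max >= threshold)


def fixed_threshold(value: float) -> KinThreshold:
    """A fixed (externally supplied) close-kin threshold."""
    return KinThreshold(threshold=float(value), source="fixed",
                        known_kin_min=float("nan"), known_nonkin_max=float("-inf"),
                        overlap=False)


@dataclass
class TieSet:
    """Genetic ties (dyads with R strictly above the threshold) plus the
    dyads that could not be evaluated for lack of shared loci."""

    edges: pd.DataFrame          # id1, id2, R
    unevaluable: pd.DataFrame    # id1, id2, n_loci
    threshold: KinThreshold

    def pairs(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b in zip(self.edges["id1"], self.edges["id2"])}

    def to_csv(self, path) -> None:
        self.edges.to_csv(path, index=False, float_format="%.10g")


def classify_genetic_ties(rmat: RelatednessMatrix,
                          threshold: KinThreshold) -> TieSet:
    """A dyad is a genetic tie iff its R estimate exists and is strictly
    greater than the threshold (R equal to the threshold is not a tie)."""
    if not np.isfinite(threshold.threshold):
        raise ValueError("threshold must be finite")
    edge_rows, bad_rows = [], []
    n = len(rmat.ids)
    for i in range(n):
        for j in range(i + 1, n):
            v = rmat.r[i, j]
            if np.isnan(v):
                bad_rows.append((rmat.ids[i], rmat.ids[j], int(rmat.n_shared[i, j])))
            elif v > threshold.threshold:
                edge_rows.append((rmat.ids[i], rmat.ids[j], float(v)))
    return TieSet(edges=pd.DataFrame(edge_rows, columns=["id1", "id2", "R"]),
                  unevaluable=pd.DataFrame(bad_rows, columns=["id1", "id2", "n_loci"]),
                  threshold=threshold)
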
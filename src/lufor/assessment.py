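"""Stratified ("good practices") accuracy and area estimation.

Map classes are the strata; stratum weights are their mapped-area shares.
From a per-stratum sample of reference labels the estimator forms the
area-proportion matrix

    p_ij = W_i * n_ij / n_i.     (rows i = map stratum, cols j = reference)

Overall accuracy is the trace, user's accuracy p_ii / p_i., producer's
accuracy p_jj / p_.j, and the error-adjusted area of class j is
A_total * p_.j. Standard errors follow the stratified estimator for
proportions (Olofsson et al. 2014): the package validates them against a
census oracle in its tests rather than against published numbers. With a
census (every pixel sampled) the point estimates equal the exhaustive
confusion-matrix values exactly.

Accuracy is assessed per lustrum (2001-2005, 2006-2010, 2011-2015,
2016-2020) by binning loss pixels on their loss year and estimating each
bin independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from lufor.model import NODATA_CLASS


@dataclass(frozen=True)
class StratumSpec:
    class_id: int
    mapped_area: float
    weight: float

    def __post_init__(self):
        if self.mapped_area < 0 or self.weight < 0:
            raise ValueError("areas and weights must be nonnegative")


@dataclass
class ErrorMatrixEstimate:
    p_hat: np.ndarray            # (K, K) area proportions, rows=map strata
    sample_counts: np.ndarray    # (K, K) n_ij
    weights: np.ndarray          # (K,) stratum weights W_i
    overall_accuracy: float
    overall_se: float
    users: np.ndarray
    users_se: np.ndarray
    producers: np.ndarray
    producers_se: np.ndarray
    adjusted_area: np.ndarray
    adjusted_area_se: np.ndarray
    total_area: float
    z: float = 1.96

    def area_confidence_intervals(self) -> np.ndarray:
        """(K, 2) lower/upper CI bounds at the configured z."""
        half = self.z * self.adjusted_area_se
        return np.stack([self.adjusted_area - half, self.adjusted_area + half], axis=1)


@dataclass(frozen=True)
class LustrumPartition:
    """Four five-year bins covering 2001-2020; bin numbers are 1-based."""

    bins: Tuple[Tuple[int, int], ...] = (
        (2001, 2005), (2006, 2010), (2011, 2015), (2016, 2020),
    )

    def __post_init__(self):
        years = [y for lo, hi in self.bins for y in range(lo, hi + 1)]
        if sorted(years) != list(range(self.bins[0][0], self.bins[-1][1] + 1)):
            raise ValueError("bins must be disjoint and cover the range")

    def bin_of(self, year) -> np.ndarray:
        """1-based lustrum number per year; 0 for years outside all bins."""
        year = np.asarray(year)
        out = np.zeros(year.shape, dtype=np.int16)
        for b, (lo, hi) in enumerate(self.bins, start=1):
            out[(year >= lo) & (year <= hi)] = b
        return out

    def labels(self) -> List[str]:
        return [f"{lo}-{hi}" for lo, hi in self.bins]


def strata_weights(mapped_areas: Dict[int, float]) -> List[StratumSpec]:
    """Stratum weights W_h = area_h / total area."""
    areas = {int(c): float(a) for c, a in mapped_areas.items()}
    if any(a < 0 for a in areas.values()):
        raise ValueError("areas must be nonnegative")
    total = sum(areas.values())
    if total <= 0:
        raise ValueError("total mapped area must be positive")
    return [StratumSpec(c, a, a / total) for c, a in sorted(areas.items())]


def allocate_samples(
    weights: Sequence[float], n_total: int, n_min: int = 1,
) -> np.ndarray:
    """Proportional allocation, largest-remainder rounding, raised to a
    per-stratum minimum (deficits taken from the largest allocations)."""
    w = np.asarray(weights, dtype=float)
    k = w.size
    if n_total < k * n_min:
        raise ValueError(f"n_total={n_total} cannot satisfy n_min={n_min} over {k} strata")
    ideal = w / w.sum() * n_total
    counts = np.floor(ideal).astype(int)
    remainder = n_total - counts.sum()
    if remainder > 0:
        order = np.argsort(-(ideal - counts))
        counts[order[:remainder]] += 1
    while (counts < n_min).any():
        deficit = np.flatnonzero(counts < n_min)[0]
        donor = int(np.argmax(counts))
        if counts[donor] <= n_min:
            raise ValueError("infeasible n_min")
        counts[donor] -= 1
        counts[deficit] += 1
    return counts


def _group_samples(
    samples: Sequence[Tuple[int, int]], k: int,
) -> np.ndarray:
    """(map_label, reference_label) pairs -> (K, K) count matrix n_ij."""
    n = np.zeros((k, k), dtype=np.int64)
    for m, r in samples:
        n[int(m), int(r)] += 1
    return n


def stratified_estimates(
    samples: Sequence[Tuple[int, int]],
    strata: Sequence[StratumSpec],
    total_area: float,
    z: float = 1.96,
) -> ErrorMatrixEstimate:
    """Accuracy and error-adjusted areas with standard errors.

    ``samples`` are (map label, reference label) pairs; every stratum with
    positive weight must be sampled at least once.
    """
    if total_area <= 0:
        raise ValueError("total_area must be positive")
    k = max(s.class_id for s in strata) + 1
    w = np.zeros(k)
    area = np.zeros(k)
    for s in strata:
        w[s.class_id] = s.weight
        area[s.class_id] = s.mapped_area
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("stratum weights must sum to 1")
    n = _group_samples(samples, k)
    ni = n.sum(axis=1).astype(float)
    unsampled = (w > 0) & (ni == 0)
    if unsampled.any():
        raise ValueError(f"unsampled strata: {np.flatnonzero(unsampled).tolist()}")

    ni_safe = np.where(ni > 0, ni, 1.0)
    prop = n / ni_safe[:, None]                 # n_ij / n_i.
    p_hat = w[:, None] * prop
    overall = float(np.trace(p_hat))
    p_row = p_hat.sum(axis=1)
    p_col = p_hat.sum(axis=0)
    diag = np.diag(p_hat)
    users = np.divide(diag, p_row, out=np.zeros(k), where=p_row > 0)
    producers = np.divide(diag, p_col, out=np.zeros(k), where=p_col > 0)

    # variance terms use n_i - 1 in the denominator; strata with a single
    # sample report zero variance rather than dividing by zero
    nm1 = np.where(ni > 1, ni - 1.0, np.inf)
    var_users = users * (1 - users) / nm1
    users_se = np.sqrt(var_users)
    overall_se = float(np.sqrt(np.sum(w**2 * users * (1 - users) / nm1)))

    # SE of the reference-class column totals -> adjusted-area SE
    var_col = np.sum(w[:, None] ** 2 * prop * (1 - prop) / nm1[:, None], axis=0)
    col_se = np.sqrt(var_col)
    adjusted_area = total_area * p_col
    adjusted_area_se = total_area * col_se

    # producer's accuracy variance (Olofsson et al. 2014, eq. 7), using
    # mapped areas as the N_i totals
    prod_se = np.zeros(k)
    n_hat_col = np.sum(area[:, None] * prop, axis=0)  # estimated reference totals
    for j in range(k):
        if p_col[j] <= 0 or n_hat_col[j] <= 0:
            continue
        t1 = (area[j] ** 2 * (1 - producers[j]) ** 2
              * users[j] * (1 - users[j]) / nm1[j])
        others = [i for i in range(k) if i != j and ni[i] > 0]
        t2 = producers[j] ** 2 * sum(
            area[i] ** 2 * prop[i, j] * (1 - prop[i, j]) / nm1[i] for i in others
        )
        prod_se[j] = np.sqrt((t1 + t2)) / n_hat_col[j]

    return ErrorMatrixEstimate(
        p_hat=p_hat,
        sample_counts=n,
        weights=w,
        overall_accuracy=overall,
        overall_se=overall_se,
        users=users,
        users_se=users_se,
        producers=producers,
        producers_se=prod_se,
        adjusted_area=adjusted_area,
        adjusted_area_se=adjusted_area_se,
        total_area=total_area,
        z=z,
    )


def sample_reference(
    class_map: np.ndarray,
    reference_map: np.ndarray,
    counts: Dict[int, int],
    seed: int = 0,
    interpreter_error_rate: float = 0.0,
    n_classes: Optional[int] = None,
) -> List[Tuple[int, int]]:
    """Draw a per-stratum random sample of (map, reference) label pairs.

    The reference interpreter is the generator's clean truth by default; a
    positive interpreter_error_rate flips that fraction of reference labels
    to a random other class to emulate interpreter noise.
    """
    rng = np.random.default_rng(seed)
    class_map = np.asarray(class_map)
    reference_map = np.asarray(reference_map)
    k = n_classes or int(max(class_map[class_map != NODATA_CLASS].max(),
                             reference_map.max())) + 1
    out: List[Tuple[int, int]] = []
    for cid in sorted(counts):
        idx = np.flatnonzero(class_map.ravel() == cid)
        if idx.size == 0:
            raise ValueError(f"stratum {cid} has no mapped pixels")
        pick = rng.choice(idx, size=min(counts[cid], idx.size),
                          replace=counts[cid] > idx.size)
        refs = reference_map.ravel()[pick].astype(int)
        if interpreter_error_rate > 0:
            flip = rng.uniform(size=refs.size) < interpreter_error_rate
            refs[flip] = (refs[flip] + rng.integers(1, k, size=int(flip.sum()))) % k
        out.extend((cid, int(r)) for r in refs)
    return out


def per_lustrum_assessment(
    class_map: np.ndarray,
    loss_year: np.ndarray,
    reference_map: np.ndarray,
    partition: LustrumPartition = LustrumPartition(),
    n_total: int = 200,
    n_min: int = 5,
    pixel_area_ha: float = 0.0025,
    seed: int = 0,
    interpreter_error_rate: float = 0.0,
) -> Dict[int, Optional[ErrorMatrixEstimate]]:
    """Independent stratified estimate per lustrum bin.

    Pixels enter a bin by their loss year; only classified (non-no-data)
    loss pixels count. Empty bins are reported as None. Returns a dict
    keyed by 1-based lustrum number.
    """
    class_map = np.asarray(class_map)
    loss_year = np.asarray(loss_year)
    if class_map.shape != loss_year.shape:
        raise ValueError("class_map and loss_year must align")
    bins = partition.bin_of(loss_year)
    results: Dict[int, Optional[ErrorMatrixEstimate]] = {}
    rng = np.random.default_rng(seed)
    for b in range(1, len(partition.bins) + 1):
        sel = (bins == b) & (class_map != NODATA_CLASS)
        if not sel.any():
            results[b] = None
            continue
        sub_map = np.where(sel, class_map, NODATA_CLASS)
        ids, counts = np.unique(class_map[sel], return_counts=True)
        areas = {int(c): float(cnt) * pixel_area_ha for c, cnt in zip(ids, counts)}
        strata = strata_weights(areas)
        weights = [s.weight for s in strata]
        n_eff = max(n_total, len(strata) * n_min)
        alloc = allocate_samples(weights, n_eff, n_min)
        counts_by_class = {s.class_id: int(a) for s, a in zip(strata, alloc)}
        samples = sample_reference(
            sub_map, reference_map, counts_by_class,
            seed=int(rng.integers(0, 2**31 - 1)),
            interpreter_error_rate=interpreter_error_rate,
        )
        results[b] = stratified_estimates(samples, strata, total_area=sum(areas.values()))
    return results
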
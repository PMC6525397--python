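"""Unification of ROIs across runs and column-wise matrix augmentation.

Simultaneous multi-sample resolution needs one spectral (column) basis shared
by all runs, while each run keeps its own block of rows (scans).  ROI search
on different runs yields different ROI sets, so the sets are unified pairwise:

1. center m/z values of the two inputs coincident within ±mzerror are merged;
   the unified center is the average of the two matched values;
2. the matched columns are stacked (if several columns of one side coincide
   with one target their intensities are summed row-wise);
3. a non-coincident column is kept only if its maximum intensity exceeds the
   signal threshold; its missing block in the other run is filled with small
   positive random values (1% of the threshold on average);
4. non-coincident columns that never rise above the threshold are dropped;
5. columns are re-sorted by the unified center m/z.

Folding this pairwise step over K runs yields the column-wise augmented
matrix D_aug of shape (sum of scan counts) x n_aug, where each run's rows are
a contiguous block.  No retention-time alignment is performed — the
downstream bilinear model shares spectra, not elution profiles, across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msio import ValidationError
from .roi_search import ROIParams, ROISet

__all__ = ["AugmentedROISet", "augment_pair", "augment_all"]


@dataclass
class AugmentedROISet:
    """Column-wise augmented intensity matrix over multiple runs.

    ``msroi_aug`` has one row block per run (``boundaries`` maps each run to
    its half-open row range) and one column per unified ROI center in
    ``mzroi`` (strictly increasing).
    """

    sample_ids: list[str]
    mzroi: np.ndarray
    msroi_aug: np.ndarray
    boundaries: list[tuple[int, int]]
    scan_counts: np.ndarray
    times: np.ndarray
    params: ROIParams | None = None

    def __post_init__(self) -> None:
        self.mzroi = np.asarray(self.mzroi, dtype=float)
        self.msroi_aug = np.asarray(self.msroi_aug, dtype=float)
        self.scan_counts = np.asarray(self.scan_counts, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        if self.msroi_aug.shape[0] != int(self.scan_counts.sum()):
            raise ValidationError("row count != sum of scan counts")
        if len(self.boundaries) != len(self.sample_ids):
            raise ValidationError("boundaries/sample_ids length mismatch")
        if self.mzroi.size > 1 and np.any(np.diff(self.mzroi) <= 0):
            raise ValidationError("unified mzroi must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_rois(self) -> int:
        return len(self.mzroi)

    def block(self, k: int) -> np.ndarray:
        a, b = self.boundaries[k]
        return self.msroi_aug[a:b]


def _as_augmented(x: ROISet | AugmentedROISet) -> AugmentedROISet:
    if isinstance(x, AugmentedROISet):
        return x
    m = len(x.times)
    return AugmentedROISet(
        sample_ids=[x.sample_id],
        mzroi=x.mzroi.copy(),
        msroi_aug=x.msroi.copy(),
        boundaries=[(0, m)],
        scan_counts=np.array([m]),
        times=x.times.copy(),
        params=x.params,
    )


def _match_centers(
    mz_a: np.ndarray, mz_b: np.ndarray, mzerror: float
) -> list[tuple[int, int]]:
    """One-to-one greedy matching of two sorted center lists: candidate pairs
    within mzerror are accepted nearest-first, each center used once."""
    pairs = []
    for i, ma in enumerate(mz_a):
        lo = np.searchsorted(mz_b, ma - mzerror)
        hi = np.searchsorted(mz_b, ma + mzerror, side="right")
        for j in range(lo, hi):
            pairs.append((abs(ma - mz_b[j]), i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((i, j))
    return matches


def augment_pair(
    a: ROISet | AugmentedROISet,
    b: ROISet | AugmentedROISet,
    params: ROIParams,
    allow_params_mismatch: bool = False,
) -> AugmentedROISet:
    """Unify two ROI results (single-run or already augmented) into one
    column-wise augmented matrix; ``a``'s row blocks come first."""
    A, B = _as_augmented(a), _as_augmented(b)
    if set(A.sample_ids) & set(B.sample_ids):
        raise ValidationError("sample ids of the two inputs must be disjoint")
    for side in (A, B):
        if side.params is not None and not allow_params_mismatch:
            if (
                side.params.mzerror != params.mzerror
                or side.params.thresh != params.thresh
            ):
                raise ValidationError(
                    "input built with different mzerror/thresh than requested; "
                    "pass allow_params_mismatch=True to override"
                )

    m_a, m_b = A.msroi_aug.shape[0], B.msroi_aug.shape[0]
    matches = _match_centers(A.mzroi, B.mzroi, params.mzerror)
    matched_a = {i for i, _ in matches}
    matched_b = {j for _, j in matches}

    # center m/z, column over a-rows (or None => fill), column over b-rows
    columns: list[tuple[float, np.ndarray | None, np.ndarray | None]] = []
    for i, j in matches:
        center = 0.5 * (A.mzroi[i] + B.mzroi[j])
        columns.append((center, A.msroi_aug[:, i].copy(), B.msroi_aug[:, j].copy()))
    for i in range(A.n_rois):
        if i not in matched_a:
            columns.append((float(A.mzroi[i]), A.msroi_aug[:, i].copy(), None))
    for j in range(B.n_rois):
        if j not in matched_b:
            columns.append((float(B.mzroi[j]), None, B.msroi_aug[:, j].copy()))

    # leftover multi-matches: an unmatched center still within mzerror of an
    # already-merged center is summed into that column rather than kept alone
    columns.sort(key=lambda c: c[0])
    merged: list[tuple[float, np.ndarray | None, np.ndarray | None]] = []
    for center, col_a, col_b in columns:
        if merged and (col_a is None or col_b is None):
            pc, pa, pb = merged[-1]
            if pa is not None and pb is not None and abs(center - pc) <= params.mzerror:
                if col_a is not None:
                    pa += col_a
                if col_b is not None:
                    pb += col_b
                continue
        merged.append((center, col_a, col_b))

    # threshold filter for columns absent on one side, then fill that block
    rng = np.random.default_rng(params.seed)
    hi = 2.0 * params.fill_fraction * params.thresh

    def _fill(n: int) -> np.ndarray:
        draws = rng.uniform(0.0, hi, size=n)
        draws[draws == 0.0] = hi / 2.0
        return draws

    kept: list[tuple[float, np.ndarray]] = []
    for center, col_a, col_b in merged:
        if col_a is None or col_b is None:
            present = col_b if col_a is None else col_a
            if present.max() <= params.thresh:
                continue
            if col_a is None:
                col_a = _fill(m_a)
            else:
                col_b = _fill(m_b)
        kept.append((center, np.concatenate([col_a, col_b])))

    kept.sort(key=lambda c: c[0])
    mzroi = np.array([c for c, _ in kept])
    if kept:
        msroi_aug = np.column_stack([col for _, col in kept])
    else:
        msroi_aug = np.zeros((m_a + m_b, 0))

    boundaries = list(A.boundaries) + [(s + m_a, e + m_a) for s, e in B.boundaries]
    return AugmentedROISet(
        sample_ids=list(A.sample_ids) + list(B.sample_ids),
        mzroi=mzroi,
        msroi_aug=msroi_aug,
        boundaries=boundaries,
        scan_counts=np.concatenate([A.scan_counts, B.scan_counts]),
        times=np.concatenate([A.times, B.times]),
        params=params,
    )


def augment_all(
    sets: list[ROISet | AugmentedROISet],
    params: ROIParams,
    plan: str = "sequential",
    groups: list[str] | None = None,
    allow_params_mismatch: bool = False,
) -> AugmentedROISet:
    """Fold :func:`augment_pair` over a list of ROI results.

    ``plan="sequential"`` augments in the given order; ``plan="grouped"``
    (with per-set ``groups`` labels) first augments within each group, then
    across groups — e.g. controls first, then exposed, then both together.
    """
    if len(sets) < 2:
        raise ValidationError("need at least two ROI sets to augment")
    if plan == "sequential":
        acc = sets[0]
        for nxt in sets[1:]:
            acc = augment_pair(acc, nxt, params, allow_params_mismatch)
        return _as_augmented(acc)
    if plan == "grouped":
        if groups is None or len(groups) != len(sets):
            raise ValidationError("grouped plan needs one group label per set")
        order = list(dict.fromkeys(groups))  # preserve first-appearance order
        partials: list[ROISet | AugmentedROISet] = []
        for g in order:
            members = [s for s, lab in zip(sets, groups) if lab == g]
            if len(members) == 1:
                partials.append(members[0])
            else:
                partials.append(
                    augment_all(members, params, "sequential",
                                allow_params_mismatch=allow_params_mismatch)
                )
        if len(partials) == 1:
            return _as_augmented(partials[0])
        return augment_all(partials, params, "sequential",
                           allow_params_mismatch=allow_params_mismatch)
    raise ValidationError(f"unknown augmentation plan {plan!r}")
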
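"""Shared fixtures: tiny hand-built runs, random micro-runs, and an
independent brute-force ROI oracle used to cross-check the scan-by-scan
search."""

from __future__ import annotations

import numpy as np
import pytest

from roimcr import ROIParams, ScanList


@pytest.fixture
def three_scan_run() -> ScanList:
    """Two clean ions present in all three scans (hand-traceable)."""
    times = np.array([1.0, 2.0, 3.0])
    scans = [
        (np.array([100.00, 200.00]), np.array([1000.0, 800.0])),
        (np.array([100.00, 200.00]), np.array([1000.0, 800.0])),
        (np.array([100.00, 200.00]), np.array([1000.0, 800.0])),
    ]
    return ScanList("tiny", times, scans)


@pytest.fixture
def default_params() -> ROIParams:
    return ROIParams(thresh=500.0, mzerror=0.05, minroi=3, seed=0)


def random_micro_run(rng: np.random.Generator) -> tuple[ScanList, ROIParams]:
    """A random run of <=5 scans with <=8 points each, m/z drawn from a
    narrow window so cluster/merge/tie edge cases actually occur."""
    n_scans = int(rng.integers(1, 6))
    times = np.cumsum(rng.uniform(0.5, 2.0, size=n_scans))
    scans = []
    for _ in range(n_scans):
        n_pts = int(rng.integers(0, 9))
        mz = np.sort(rng.uniform(100.0, 100.6, size=n_pts))
        inten = rng.uniform(0.0, 1500.0, size=n_pts)
        scans.append((mz, inten))
    params = ROIParams(
        thresh=500.0,
        mzerror=float(rng.choice([0.03, 0.05, 0.1, 0.15])),
        minroi=int(rng.integers(1, 4)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return ScanList("micro", times, scans), params


# ---------------------------------------------------------------------------
# brute-force oracle: plain lists, centers recomputed exhaustively from all
# members at every step — no running statistics, no vectorization


def oracle_find_rois(run: ScanList, params: ROIParams):
    """Returns (centers, members): members[i] is the list of
    (scan, mz, intensity) points of ROI i, in admission order."""
    assert params.center == "mean"
    rois: list[list[tuple[int, float, float]]] = []

    def center(points) -> float:
        return sum(p[1] for p in points) / len(points)

    for scan_idx, (mz, inten) in enumerate(run.scans):
        pts = [
            (scan_idx, float(m), float(v))
            for m, v in zip(mz, inten)
            if v > params.thresh
        ]
        pts.sort(key=lambda p: p[1])
        # greedy ascending clustering against the cluster's full mean
        clusters: list[list[tuple[int, float, float]]] = []
        for p in pts:
            if clusters and abs(p[1] - center(clusters[-1])) <= params.mzerror:
                clusters[-1].append(p)
            else:
                clusters.append([p])
        for cl in clusters:
            c = center(cl)
            best = None
            for i, roi in enumerate(rois):
                rc = center(roi)
                d = abs(rc - c)
                if d <= params.mzerror and (
                    best is None
                    or d < best[0]
                    or (d == best[0] and rc < best[2])
                ):
                    best = (d, i, rc)
            if best is None:
                rois.append(list(cl))
            else:
                rois[best[1]].extend(cl)

    # exhaustive closest-pair merging of drifted centers
    while len(rois) > 1:
        rois.sort(key=center)
        gaps = [
            (center(rois[i + 1]) - center(rois[i]), i)
            for i in range(len(rois) - 1)
        ]
        gap, i = min(gaps)
        if gap > params.mzerror:
            break
        rois[i].extend(rois.pop(i + 1))

    kept = [
        roi
        for roi in rois
        if len({p[0] for p in roi}) >= params.minroi
    ]
    kept.sort(key=center)
    return [center(roi) for roi in kept], kept
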
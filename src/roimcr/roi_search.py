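"""Region-of-interest (ROI) search, filtering and compression on one run.

An ROI is a cluster of raw (scan, m/z, intensity) points whose intensity
exceeds a signal threshold, whose m/z values stay within a mass-error
tolerance of the cluster's running center, and which persists for a minimum
number of scans.  The search walks the run scan by scan:

1. keep points with intensity above ``thresh`` in the current scan;
2. group them into clusters within ``mzerror`` of the cluster's running
   center (points taken in ascending m/z);
3. compute each cluster's center m/z (mean, or median on request);
4. match clusters against the centers of ROIs opened by earlier scans,
   within ``mzerror``; a matched cluster joins that ROI and the center is
   updated over all members, an unmatched cluster opens a new ROI;
5. after the last scan, ROIs whose centers drifted within ``mzerror`` of
   each other are merged, ROIs observed in fewer than ``minroi`` scans are
   dropped, and survivors are sorted by center m/z;
6. the dense scans x ROIs intensity matrix (``msroi``) is assembled —
   multiple members of one ROI in one scan are summed — and remaining empty
   cells are replaced by small positive random values (see
   :func:`fill_missing`), so downstream factorization never sees exact zeros.

Compression is lossless in the m/z direction: the full mass accuracy of each
member point is retained in the per-ROI provenance records (``roicell``),
no binning grid is imposed and no peak shape is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msio import ScanList, ValidationError

__all__ = [
    "ROIParams",
    "ROICell",
    "ROISet",
    "find_rois",
    "fill_missing",
    "roi_trace",
    "threshold_from_max",
]


@dataclass(frozen=True)
class ROIParams:
    """Parameters of the ROI search.

    thresh:
        Signal threshold in absolute intensity units; only points above it
        enter the search.  A practical starting point is 0.1–1% of the run's
        maximum intensity (see :func:`threshold_from_max`).
    mzerror:
        Mass error tolerance in Da/e; controls both in-scan clustering and
        across-scan matching.
    minroi:
        Minimum number of occurrences (scans containing at least one member)
        for an ROI to survive.  Tie it to the expected chromatographic peak
        width: ``peak width (s) / scan interval (s)``.
    fill_fraction:
        Mean of the fill-in values for empty cells, as a fraction of
        ``thresh`` (default 1%).
    center:
        Statistic used for cluster/ROI centers: ``"mean"`` or ``"median"``.
    occurrence_mode:
        ``"total"`` counts all scans with a member; ``"consecutive"`` counts
        the longest consecutive scan run.
    seed:
        Seed for the fill-in random values.
    """

    thresh: float
    mzerror: float
    minroi: int = 10
    fill_fraction: float = 0.01
    center: str = "mean"
    occurrence_mode: str = "total"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.thresh > 0:
            raise ValidationError("thresh must be > 0")
        if not self.mzerror > 0:
            raise ValidationError("mzerror must be > 0")
        if self.minroi < 1:
            raise ValidationError("minroi must be >= 1")
        if not 0 < self.fill_fraction < 1:
            raise ValidationError("fill_fraction must be in (0, 1)")
        if self.center not in {"mean", "median"}:
            raise ValidationError("center must be 'mean' or 'median'")
        if self.occurrence_mode not in {"total", "consecutive"}:
            raise ValidationError("occurrence_mode must be 'total' or 'consecutive'")

    def to_dict(self) -> dict:
        return {
            "thresh": self.thresh,
            "mzerror": self.mzerror,
            "minroi": self.minroi,
            "fill_fraction": self.fill_fraction,
            "center": self.center,
            "occurrence_mode": self.occurrence_mode,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ROIParams":
        return cls(**d)


def threshold_from_max(scans: ScanList, fraction: float = 0.002) -> float:
    """Absolute threshold as a fraction of the run's maximum intensity."""
    if not 0 < fraction < 1:
        raise ValidationError("fraction must be in (0, 1)")
    peak = scans.max_intensity()
    if peak <= 0:
        raise ValidationError("run has no positive intensities")
    return fraction * peak


@dataclass
class ROICell:
    """Provenance record of one ROI: its member points and center m/z."""

    mz: np.ndarray
    rt: np.ndarray
    intensity: np.ndarray
    scan: np.ndarray
    center: float

    @property
    def n_members(self) -> int:
        return len(self.mz)

    def occurrences(self, mode: str = "total") -> int:
        distinct = np.unique(self.scan)
        if mode == "total":
            return len(distinct)
        # longest run of consecutive scan indices
        best = run = 1
        for a, b in zip(distinct[:-1], distinct[1:]):
            run = run + 1 if b == a + 1 else 1
            best = max(best, run)
        return best


@dataclass
class ROISet:
    """Result of an ROI search on one run.

    ``mzroi`` holds the n ROI center m/z values (strictly increasing),
    ``msroi`` the dense scans x n intensity matrix (all entries positive after
    fill-in) and ``roicell`` the per-ROI provenance records.
    """

    sample_id: str
    times: np.ndarray
    mzroi: np.ndarray
    msroi: np.ndarray
    roicell: list[ROICell]
    params: ROIParams | None = None
    filled_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mzroi = np.asarray(self.mzroi, dtype=float)
        self.msroi = np.asarray(self.msroi, dtype=float)
        if self.msroi.shape != (len(self.times), len(self.mzroi)):
            raise ValidationError(
                f"msroi shape {self.msroi.shape} != "
                f"({len(self.times)}, {len(self.mzroi)})"
            )
        if len(self.roicell) != len(self.mzroi):
            raise ValidationError("roicell length != number of ROIs")
        if self.mzroi.size > 1 and np.any(np.diff(self.mzroi) <= 0):
            raise ValidationError("mzroi must be strictly increasing")

    @property
    def n_rois(self) -> int:
        return len(self.mzroi)


class _ROI:
    """Mutable accumulator used during the scan-by-scan search."""

    __slots__ = ("mz", "rt", "intensity", "scan", "center", "stat")

    def __init__(self, stat: str) -> None:
        self.mz: list[float] = []
        self.rt: list[float] = []
        self.intensity: list[float] = []
        self.scan: list[int] = []
        self.center = 0.0
        self.stat = stat

    def admit(self, mz, rt, inten, scan_idx) -> None:
        self.mz.extend(mz)
        self.rt.extend(rt)
        self.intensity.extend(inten)
        self.scan.extend(scan_idx)
        self._update_center()

    def _update_center(self) -> None:
        self.center = (
            float(np.mean(self.mz)) if self.stat == "mean" else float(np.median(self.mz))
        )


def _cluster_scan(mz: np.ndarray, mzerror: float, stat: str) -> list[slice]:
    """Greedy in-scan clustering: ascending m/z, a point joins the open
    cluster while it stays within mzerror of the cluster's running center."""
    bounds: list[slice] = []
    start = 0
    if stat == "mean":
        csum = 0.0
        for i, m in enumerate(mz):
            if i > start and abs(m - csum / (i - start)) > mzerror:
                bounds.append(slice(start, i))
                start = i
                csum = 0.0
            csum += m
    else:
        for i, m in enumerate(mz):
            if i > start and abs(m - float(np.median(mz[start:i]))) > mzerror:
                bounds.append(slice(start, i))
                start = i
    if len(mz):
        bounds.append(slice(start, len(mz)))
    return bounds


def find_rois(scans: ScanList, params: ROIParams) -> ROISet:
    """Run the ROI searching, filtering and compression algorithm on one run.

    Returns an :class:`ROISet`; see the module docstring for the algorithm.
    Raises :class:`~roimcr.msio.ValidationError` on an empty run.
    """
    if scans.n_scans == 0:
        raise ValidationError("run contains no scans")

    rois: list[_ROI] = []
    for scan_idx, (mz, inten) in enumerate(scans.scans):
        keep = inten > params.thresh
        if not np.any(keep):
            continue
        mz_f, inten_f = mz[keep], inten[keep]
        rt = scans.times[scan_idx]
        # clusters arrive in ascending m/z; centers queried live so an
        # admission immediately shifts the target for the next cluster
        for sl in _cluster_scan(mz_f, params.mzerror, params.center):
            cmz = mz_f[sl]
            c_center = (
                float(np.mean(cmz)) if params.center == "mean" else float(np.median(cmz))
            )
            target = None
            if rois:
                centers = np.array([r.center for r in rois])
                dist = np.abs(centers - c_center)
                j = int(np.argmin(dist))
                # exact distance ties go to the lower-m/z center
                ties = np.nonzero(dist == dist[j])[0]
                if len(ties) > 1:
                    j = int(ties[np.argmin(centers[ties])])
                if dist[j] <= params.mzerror:
                    target = rois[j]
            if target is None:
                target = _ROI(params.center)
                rois.append(target)
            target.admit(
                cmz,
                [rt] * len(cmz),
                inten_f[sl],
                [scan_idx] * len(cmz),
            )

    _merge_close(rois, params.mzerror)
    rois = [r for r in rois if _occurrences(r, params.occurrence_mode) >= params.minroi]
    rois.sort(key=lambda r: r.center)

    n = len(rois)
    m = scans.n_scans
    msroi = np.zeros((m, n))
    roicell: list[ROICell] = []
    for j, r in enumerate(rois):
        scan_arr = np.asarray(r.scan, dtype=int)
        inten_arr = np.asarray(r.intensity, dtype=float)
        np.add.at(msroi[:, j], scan_arr, inten_arr)
        roicell.append(
            ROICell(
                mz=np.asarray(r.mz, dtype=float),
                rt=np.asarray(r.rt, dtype=float),
                intensity=inten_arr,
                scan=scan_arr,
                center=r.center,
            )
        )

    empty = msroi == 0
    msroi = fill_missing(msroi, params)
    return ROISet(
        sample_id=scans.sample_id,
        times=scans.times.copy(),
        mzroi=np.array([r.center for r in rois]),
        msroi=msroi,
        roicell=roicell,
        params=params,
        filled_mask=empty,
    )


def _occurrences(roi: _ROI, mode: str) -> int:
    distinct = np.unique(roi.scan)
    if mode == "total":
        return len(distinct)
    best = run = 1
    for a, b in zip(distinct[:-1], distinct[1:]):
        run = run + 1 if b == a + 1 else 1
        best = max(best, run)
    return best


def _merge_close(rois: list[_ROI], mzerror: float) -> None:
    """Pool ROIs whose centers drifted within mzerror of each other,
    closest pair first, recomputing centers after each merge."""
    while len(rois) > 1:
        rois.sort(key=lambda r: r.center)
        gaps = [
            (rois[i + 1].center - rois[i].center, i) for i in range(len(rois) - 1)
        ]
        gap, i = min(gaps)
        if gap > mzerror:
            break
        a, b = rois[i], rois[i + 1]
        a.admit(b.mz, b.rt, b.intensity, b.scan)
        del rois[i + 1]


def fill_missing(msroi: np.ndarray, params: ROIParams) -> np.ndarray:
    """Replace empty (zero) cells with independent uniform draws on
    ``(0, 2*fill_fraction*thresh)`` — mean ``fill_fraction*thresh`` — so the
    matrix carries a small positive noise floor instead of exact zeros.
    Non-empty cells are untouched; deterministic given ``params.seed``."""
    msroi = np.asarray(msroi, dtype=float)
    empty = msroi == 0
    n_empty = int(empty.sum())
    if n_empty == 0:
        return msroi.copy()
    rng = np.random.default_rng(params.seed)
    hi = 2.0 * params.fill_fraction * params.thresh
    out = msroi.copy()
    draws = rng.uniform(0.0, hi, size=n_empty)
    draws[draws == 0.0] = hi / 2.0  # open interval
    out[empty] = draws
    return out


def roi_trace(roiset: ROISet, index: int):
    """Extract one ROI's elution profile and raw mass-trace points.

    Returns ``(profile, members)`` where ``profile`` is the msroi column over
    the retention-time grid and ``members`` is an (k, 3) array of
    ``(rt, mz, intensity)`` triples taken verbatim from the provenance
    record — suitable for plotting the elution curve and the m/z-vs-time
    mass trace side by side.
    """
    if not 0 <= index < roiset.n_rois:
        raise IndexError(
            f"ROI index {index} out of range for {roiset.n_rois} ROIs"
        )
    cell = roiset.roicell[index]
    members = np.column_stack([cell.rt, cell.mz, cell.intensity])
    return roiset.msroi[:, index].copy(), members
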
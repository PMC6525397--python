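"""Reading centroided LC-MS runs and persisting pipeline artifacts.

A raw centroided run is held as a :class:`ScanList`: a retention-time vector
(seconds) plus, per scan, a pair of equal-length vectors of m/z (Da/e) and
intensity (a.u.) whose length varies from scan to scan.  Two standard input
formats are supported, mzML (PSI) and ANDI-MS netCDF ("CDF"); both are read
into the same structure, times normalised to seconds, per-scan m/z sorted
ascending (a stable sort carrying intensities).

Every pipeline artifact (ScanList, ROISet, AugmentedROISet, MCRModel,
BiomarkerTable) can be written to a *bundle*: a directory of delimited-text
matrices plus a JSON manifest, chosen over a binary container for portability
and diffability.  ``read_bundle(write_bundle(x))`` is value-identical to ``x``
(floats are encoded with 17 significant digits, i.e. bit-exact for float64).
"""

from __future__ import annotations

import base64
import json
import struct
import warnings
import zlib
from dataclasses import dataclass
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

__all__ = [
    "ScanList",
    "FormatError",
    "ValidationError",
    "read_ms_run",
    "write_mzml",
    "write_cdf",
    "write_bundle",
    "read_bundle",
]

_FLOAT_FMT = "%.17g"

# median points/scan above which input looks like profile-mode data
PROFILE_SUSPECT_POINTS = 2000


class FormatError(RuntimeError):
    """Raised when an input file cannot be parsed in the requested format."""


class ValidationError(ValueError):
    """Raised when data violate a structural invariant."""


@dataclass
class ScanList:
    """A centroided LC-MS run.

    Parameters
    ----------
    sample_id:
        Identifier of the run (file stem by default).
    times:
        Retention times in seconds, strictly increasing, one per scan.
    scans:
        One ``(mz, intensity)`` pair of equal-length float arrays per scan;
        m/z sorted ascending within each scan, intensities non-negative.
        Lengths vary between scans; empty scans are kept as empty vectors.
    """

    sample_id: str
    times: np.ndarray
    scans: list[tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.scans = [
            (np.asarray(mz, dtype=float), np.asarray(inten, dtype=float))
            for mz, inten in self.scans
        ]
        self.validate()

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    def scan_lengths(self) -> np.ndarray:
        return np.array([len(mz) for mz, _ in self.scans], dtype=int)

    def max_intensity(self) -> float:
        vals = [inten.max() for _, inten in self.scans if inten.size]
        return float(max(vals)) if vals else 0.0

    def validate(self) -> None:
        if self.times.ndim != 1 or len(self.times) != len(self.scans):
            raise ValidationError(
                f"times (length {len(self.times)}) and scans "
                f"(length {len(self.scans)}) must align"
            )
        bad = np.nonzero(np.diff(self.times) <= 0)[0]
        if bad.size:
            raise ValidationError(
                f"retention times not strictly increasing at scan {bad[0] + 1}"
            )
        for i, (mz, inten) in enumerate(self.scans):
            if mz.shape != inten.shape or mz.ndim != 1:
                raise ValidationError(f"scan {i}: mz/intensity shape mismatch")
            if mz.size and np.any(np.diff(mz) < 0):
                raise ValidationError(f"scan {i}: m/z not sorted ascending")
            if inten.size and inten.min() < 0:
                raise ValidationError(f"scan {i}: negative intensity")


def _sort_scan(mz: np.ndarray, inten: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(mz, kind="stable")
    return mz[order], inten[order]


# ---------------------------------------------------------------------------
# readers


def read_ms_run(
    path: str | Path,
    format: str = "auto",
    sample_id: str | None = None,
    assume_centroid: bool = False,
) -> ScanList:
    """Read a centroided MS1 run from an mzML or ANDI-MS (CDF) file.

    Retention times are converted to seconds regardless of source units, scans
    are kept in file order, and each scan's m/z values are stably sorted
    ascending (carrying intensities).  Inputs that look like profile-mode data
    (median points per scan above ``PROFILE_SUSPECT_POINTS``) trigger a warning
    unless ``assume_centroid`` is set; they are never rejected outright.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "auto":
        suffix = path.suffix.lower()
        format = "cdf" if suffix in {".cdf", ".nc"} else "mzml"
    if sample_id is None:
        sample_id = path.stem

    if format == "mzml":
        times, scans = _read_mzml(path)
    elif format == "cdf":
        times, scans = _read_cdf(path)
    else:
        raise ValueError(f"unknown format {format!r}")

    if not scans:
        raise FormatError(f"{path}: no MS1 scans found")

    scans = [_sort_scan(mz, inten) for mz, inten in scans]
    run = ScanList(sample_id=sample_id, times=np.asarray(times), scans=scans)

    if not assume_centroid:
        lengths = run.scan_lengths()
        if lengths.size and np.median(lengths) > PROFILE_SUSPECT_POINTS:
            warnings.warn(
                f"{path.name}: median {int(np.median(lengths))} points/scan — "
                "input may be profile-mode; ROI search assumes centroided data",
                stacklevel=2,
            )
    return run


# mzML CV accessions used by the reader
_CV_MS_LEVEL = "MS:1000511"
_CV_SCAN_START = "MS:1000016"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INTENSITY_ARRAY = "MS:1000515"
_CV_FLOAT64 = "MS:1000523"
_CV_FLOAT32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array kind accession, values)."""
    dtype = "<f8"
    compressed = False
    kind = None
    payload = ""
    for child in bda.iter():
        name = _localname(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == _CV_FLOAT32:
                dtype = "<f4"
            elif acc == _CV_ZLIB:
                compressed = True
            elif acc in (_CV_MZ_ARRAY, _CV_INTENSITY_ARRAY):
                kind = acc
        elif name == "binary":
            payload = child.text or ""
    raw = base64.b64decode(payload)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path) -> tuple[list[float], list[tuple[np.ndarray, np.ndarray]]]:
    """Minimal mzML MS1 reader (64/32-bit float arrays, plain or zlib)."""
    import xml.etree.ElementTree as ET

    times: list[float] = []
    scans: list[tuple[np.ndarray, np.ndarray]] = []
    try:
        for _, elem in ET.iterparse(str(path), events=("end",)):
            if _localname(elem.tag) != "spectrum":
                continue
            ms_level = 1
            start_time = None
            unit = "second"
            mz = np.empty(0)
            inten = np.empty(0)
            for child in elem.iter():
                name = _localname(child.tag)
                if name == "cvParam" and child.get("accession") == _CV_MS_LEVEL:
                    ms_level = int(child.get("value", "1"))
                elif name == "cvParam" and child.get("accession") == _CV_SCAN_START:
                    start_time = float(child.get("value"))
                    unit = child.get("unitName", "minute")
                elif name == "binaryDataArray":
                    kind, values = _decode_binary_array(child)
                    if kind == _CV_MZ_ARRAY:
                        mz = values
                    elif kind == _CV_INTENSITY_ARRAY:
                        inten = values
            if ms_level == 1:
                if start_time is None:
                    raise FormatError(
                        f"{path}: spectrum {elem.get('id')} lacks a scan start time"
                    )
                seconds = start_time * 60.0 if unit.startswith("minute") else start_time
                times.append(seconds)
                scans.append((mz, inten))
            elem.clear()
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001 — surface parser failures uniformly
        raise FormatError(f"{path}: unreadable mzML ({exc})") from exc
    return times, scans


def _read_cdf(path: Path) -> tuple[list[float], list[tuple[np.ndarray, np.ndarray]]]:
    from scipy.io import netcdf_file

    try:
        with netcdf_file(str(path), "r", mmap=False) as nc:
            times = np.asarray(nc.variables["scan_acquisition_time"][:], dtype=float)
            mass = np.asarray(nc.variables["mass_values"][:], dtype=float)
            inten = np.asarray(nc.variables["intensity_values"][:], dtype=float)
            if "scan_index" in nc.variables:
                starts = np.asarray(nc.variables["scan_index"][:], dtype=int)
            else:
                counts = np.asarray(nc.variables["point_count"][:], dtype=int)
                starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    except KeyError as exc:
        raise FormatError(f"{path}: not an ANDI-MS CDF file (missing {exc})") from exc
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: unreadable netCDF ({exc})") from exc

    ends = np.concatenate([starts[1:], [len(mass)]])
    scans = [(mass[s:e], inten[s:e]) for s, e in zip(starts, ends)]
    # ANDI-MS acquisition times are already seconds
    return list(times), scans


# ---------------------------------------------------------------------------
# writers (fixtures and simulator output)


def _b64_doubles(values: np.ndarray) -> tuple[str, int]:
    raw = struct.pack(f"<{len(values)}d", *map(float, values))
    return base64.b64encode(raw).decode("ascii"), len(raw)


def write_mzml(run: ScanList, path: str | Path) -> Path:
    """Write a minimal MS1-only mzML file (64-bit float, uncompressed)."""
    path = Path(path)
    parts = [
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
        f'  <run id="{escape(run.sample_id)}">\n'
        f'    <spectrumList count="{run.n_scans}">\n'
    ]
    for i, ((mz, inten), t) in enumerate(zip(run.scans, run.times)):
        mz_b64, _ = _b64_doubles(mz)
        in_b64, _ = _b64_doubles(inten)
        parts.append(
            f'      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(mz)}">\n'
            '        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>\n'
            '        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>\n'
            '        <scanList count="1">\n'
            "          <scan>\n"
            f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{float(t)!r}"'
            ' unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>\n'
            "          </scan>\n"
            "        </scanList>\n"
            '        <binaryDataArrayList count="2">\n'
            f'          <binaryDataArray encodedLength="{len(mz_b64)}">\n'
            '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
            '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
            '            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""'
            ' unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
            f"            <binary>{mz_b64}</binary>\n"
            "          </binaryDataArray>\n"
            f'          <binaryDataArray encodedLength="{len(in_b64)}">\n'
            '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
            '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
            '            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""'
            ' unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>\n'
            f"            <binary>{in_b64}</binary>\n"
            "          </binaryDataArray>\n"
            "        </binaryDataArrayList>\n"
            "      </spectrum>\n"
        )
    parts.append("    </spectrumList>\n  </run>\n</mzML>\n")
    path.write_text("".join(parts))
    return path


def write_cdf(run: ScanList, path: str | Path) -> Path:
    """Write an ANDI-MS style netCDF-3 file (scan_acquisition_time,
    scan_index, point_count, mass_values, intensity_values)."""
    from scipy.io import netcdf_file

    path = Path(path)
    lengths = run.scan_lengths()
    total = int(lengths.sum())
    if total == 0:
        raise ValidationError("cannot write a CDF run with zero data points")
    with netcdf_file(str(path), "w") as nc:
        nc.createDimension("scan_number", run.n_scans)
        nc.createDimension("point_number", total)
        v = nc.createVariable("scan_acquisition_time", "d", ("scan_number",))
        v[:] = run.times
        v = nc.createVariable("scan_index", "i", ("scan_number",))
        v[:] = np.concatenate([[0], np.cumsum(lengths)[:-1]]).astype(np.int32)
        v = nc.createVariable("point_count", "i", ("scan_number",))
        v[:] = lengths.astype(np.int32)
        v = nc.createVariable("mass_values", "d", ("point_number",))
        v[:] = np.concatenate([mz for mz, _ in run.scans])
        v = nc.createVariable("intensity_values", "d", ("point_number",))
        v[:] = np.concatenate([inten for _, inten in run.scans])
    return path


# ---------------------------------------------------------------------------
# bundle persistence


def _save_matrix(path: Path, arr: np.ndarray) -> None:
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    np.savetxt(path, arr, fmt=_FLOAT_FMT, delimiter=",")


def _load_matrix(path: Path, shape: tuple[int, int]) -> np.ndarray:
    if 0 in shape:
        return np.zeros(shape)
    arr = np.loadtxt(path, delimiter=",", ndmin=2)
    return arr.reshape(shape)


def _save_frame(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_bundle(obj, outdir: str | Path) -> Path:
    """Persist any pipeline artifact to a directory of CSVs + manifest.json."""
    # local imports: bundle IO spans every stage of the pipeline
    from .biomarkers import BiomarkerTable
    from .mcrals import MCRModel
    from .roi_augment import AugmentedROISet
    from .roi_search import ROISet

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"format_version": 1}

    if isinstance(obj, ScanList):
        manifest.update(
            bundle_type="ScanList", sample_id=obj.sample_id, n_scans=obj.n_scans
        )
        _save_matrix(outdir / "times.csv", obj.times.reshape(1, -1))
        rows = []
        for i, (mz, inten) in enumerate(obj.scans):
            for m, v in zip(mz, inten):
                rows.append((i, obj.times[i], m, v))
        df = pd.DataFrame(rows, columns=["scan", "rt", "mz", "intensity"])
        _save_frame(outdir / "points.csv", df)
    elif isinstance(obj, ROISet):
        manifest.update(
            bundle_type="ROISet",
            sample_id=obj.sample_id,
            n_scans=len(obj.times),
            n_rois=obj.n_rois,
            params=obj.params.to_dict() if obj.params is not None else None,
        )
        _save_matrix(outdir / "times.csv", obj.times.reshape(1, -1))
        _save_matrix(outdir / "mzroi.csv", obj.mzroi.reshape(1, -1))
        _save_matrix(outdir / "msroi.csv", obj.msroi)
        rows = []
        for r, cell in enumerate(obj.roicell):
            for m, t, v, s in zip(cell.mz, cell.rt, cell.intensity, cell.scan):
                rows.append((r, int(s), t, m, v))
        df = pd.DataFrame(rows, columns=["roi", "scan", "rt", "mz", "intensity"])
        _save_frame(outdir / "roicell.csv", df)
    elif isinstance(obj, AugmentedROISet):
        manifest.update(
            bundle_type="AugmentedROISet",
            sample_ids=list(obj.sample_ids),
            scan_counts=[int(c) for c in obj.scan_counts],
            boundaries=[[int(a), int(b)] for a, b in obj.boundaries],
            n_rois=len(obj.mzroi),
            params=obj.params.to_dict() if obj.params is not None else None,
        )
        _save_matrix(outdir / "times.csv", obj.times.reshape(1, -1))
        _save_matrix(outdir / "mzroi.csv", obj.mzroi.reshape(1, -1))
        _save_matrix(outdir / "msroi_aug.csv", obj.msroi_aug)
    elif isinstance(obj, MCRModel):
        manifest.update(
            bundle_type="MCRModel",
            n_components=obj.n_components,
            lof_percent=obj.lof_percent,
            evar_percent=obj.evar_percent,
            n_iter=obj.n_iter,
            converged=obj.converged,
            boundaries=(
                [[int(a), int(b)] for a, b in obj.boundaries]
                if obj.boundaries is not None
                else None
            ),
            sample_ids=list(obj.sample_ids) if obj.sample_ids is not None else None,
            init_method=obj.init_method,
            seed=obj.seed,
            lof_history=[float(x) for x in obj.lof_history],
            collapsed_components=[int(i) for i in obj.collapsed_components],
        )
        _save_matrix(outdir / "C.csv", obj.C)
        _save_matrix(outdir / "S_T.csv", obj.S_T)
        if obj.mzroi is not None:
            _save_matrix(outdir / "mzroi.csv", obj.mzroi.reshape(1, -1))
            manifest["has_mzroi"] = True
    elif isinstance(obj, BiomarkerTable):
        manifest.update(
            bundle_type="BiomarkerTable",
            groups=list(obj.groups),
            sample_ids=list(obj.sample_ids),
            control_label=obj.control_label,
            alpha=obj.alpha,
            test=obj.test,
            mcp=obj.mcp,
        )
        _save_frame(outdir / "table.csv", obj.table)
        _save_frame(outdir / "areas.csv", obj.areas.reset_index(names="sample"))
    else:
        raise TypeError(f"cannot bundle object of type {type(obj).__name__}")

    shapes: dict[str, list[int]] = {}
    if isinstance(obj, ScanList):
        shapes["times"] = [1, obj.n_scans]
    elif isinstance(obj, ROISet):
        shapes["times"] = [1, len(obj.times)]
        shapes["mzroi"] = [1, obj.n_rois]
        shapes["msroi"] = list(obj.msroi.shape)
    elif isinstance(obj, AugmentedROISet):
        shapes["times"] = [1, len(obj.times)]
        shapes["mzroi"] = [1, len(obj.mzroi)]
        shapes["msroi_aug"] = list(obj.msroi_aug.shape)
    elif isinstance(obj, MCRModel):
        shapes["C"] = list(obj.C.shape)
        shapes["S_T"] = list(obj.S_T.shape)
        if obj.mzroi is not None:
            shapes["mzroi"] = [1, len(obj.mzroi)]
    manifest["shapes"] = shapes
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def read_bundle(indir: str | Path):
    """Load a bundle written by :func:`write_bundle` (type from the manifest)."""
    from .biomarkers import BiomarkerTable
    from .mcrals import MCRModel
    from .roi_augment import AugmentedROISet
    from .roi_search import ROICell, ROIParams, ROISet

    indir = Path(indir)
    manifest_path = indir / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"{indir}: not a bundle (no manifest.json)")
    manifest = json.loads(manifest_path.read_text())
    kind = manifest.get("bundle_type")
    shapes = manifest.get("shapes", {})

    def vec(name: str) -> np.ndarray:
        shape = shapes.get(name)
        if shape is None or shape[1] == 0:
            return np.zeros(0)
        return _load_matrix(indir / f"{name}.csv", tuple(shape)).ravel()

    if kind == "ScanList":
        times = vec("times")
        df = pd.read_csv(indir / "points.csv")
        scans = []
        for i in range(manifest["n_scans"]):
            sub = df[df["scan"] == i]
            scans.append(
                (sub["mz"].to_numpy(float), sub["intensity"].to_numpy(float))
            )
        return ScanList(manifest["sample_id"], times, scans)
    if kind == "ROISet":
        times = vec("times")
        mzroi = vec("mzroi")
        msroi = _load_matrix(
            indir / "msroi.csv", (len(times), manifest["n_rois"])
        )
        df = pd.read_csv(indir / "roicell.csv")
        roicell = []
        for r in range(manifest["n_rois"]):
            sub = df[df["roi"] == r]
            roicell.append(
                ROICell(
                    mz=sub["mz"].to_numpy(float),
                    rt=sub["rt"].to_numpy(float),
                    intensity=sub["intensity"].to_numpy(float),
                    scan=sub["scan"].to_numpy(int),
                    center=float(mzroi[r]),
                )
            )
        params = (
            ROIParams.from_dict(manifest["params"]) if manifest.get("params") else None
        )
        return ROISet(
            sample_id=manifest["sample_id"],
            times=times,
            mzroi=mzroi,
            msroi=msroi,
            roicell=roicell,
            params=params,
        )
    if kind == "AugmentedROISet":
        times = vec("times")
        mzroi = vec("mzroi")
        msroi_aug = _load_matrix(
            indir / "msroi_aug.csv", (len(times), manifest["n_rois"])
        )
        params = (
            ROIParams.from_dict(manifest["params"]) if manifest.get("params") else None
        )
        return AugmentedROISet(
            sample_ids=list(manifest["sample_ids"]),
            mzroi=mzroi,
            msroi_aug=msroi_aug,
            boundaries=[tuple(b) for b in manifest["boundaries"]],
            scan_counts=np.asarray(manifest["scan_counts"], dtype=int),
            times=times,
            params=params,
        )
    if kind == "MCRModel":
        C = _load_matrix(indir / "C.csv", tuple(shapes["C"]))
        S_T = _load_matrix(indir / "S_T.csv", tuple(shapes["S_T"]))
        mzroi = vec("mzroi") if manifest.get("has_mzroi") else None
        return MCRModel(
            C=C,
            S_T=S_T,
            n_components=manifest["n_components"],
            lof_percent=manifest["lof_percent"],
            evar_percent=manifest["evar_percent"],
            n_iter=manifest["n_iter"],
            converged=manifest["converged"],
            boundaries=(
                [tuple(b) for b in manifest["boundaries"]]
                if manifest.get("boundaries")
                else None
            ),
            sample_ids=manifest.get("sample_ids"),
            init_method=manifest.get("init_method", "purest"),
            seed=manifest.get("seed"),
            lof_history=list(manifest.get("lof_history", [])),
            collapsed_components=list(manifest.get("collapsed_components", [])),
            mzroi=mzroi,
        )
    if kind == "BiomarkerTable":
        table = pd.read_csv(indir / "table.csv")
        areas = pd.read_csv(indir / "areas.csv").set_index("sample")
        areas.index.name = None
        areas.columns = [int(c) if str(c).isdigit() else c for c in areas.columns]
        return BiomarkerTable(
            table=table,
            areas=areas,
            groups=list(manifest["groups"]),
            sample_ids=list(manifest["sample_ids"]),
            control_label=manifest["control_label"],
            alpha=manifest["alpha"],
            test=manifest["test"],
            mcp=manifest["mcp"],
        )
    raise FormatError(f"{indir}: unknown bundle type {kind!r}")
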
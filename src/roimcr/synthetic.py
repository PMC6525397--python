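"""Synthetic centroided LC-MS runs with known ground truth.

The generator emulates the structure of a real centroided acquisition: per
scan, a variable-length list of (m/z, intensity) points.  Each simulated
component has a Gaussian elution profile on the retention-time grid and a
sparse spectrum of a few ions with fixed relative abundances; at every scan
each ion contributes one point at its true m/z plus Gaussian jitter (the
instrument's mass accuracy), points below a detection floor being dropped.
Uniform-m/z baseline noise points with exponentially distributed intensities
and optional whole-scan dropouts complete the picture.  Group effects are
per-component amplitude multipliers applied to exposed runs, mirroring a
control-vs-treated study design of a few replicates per group.

Everything is deterministic given the seed, and the emitted truth
(:class:`SimTruth`) carries per-run amounts, spectra and sampled elution
profiles so every pipeline stage can be scored against what was injected.
Gaussian peaks are a property of this generator only — the pipeline itself
never assumes an elution shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msio import ScanList, ValidationError

__all__ = ["SimComponent", "SimSpec", "SimTruth", "simulate_run", "simulate_study",
           "default_spec"]


@dataclass(frozen=True)
class SimComponent:
    """One simulated analyte: a Gaussian elution peak and a sparse spectrum.

    ``spectrum`` is a list of (m/z in Da/e, relative abundance) ion pairs —
    e.g. a molecular ion plus isotope satellites or adducts.
    """

    rt_center: float  # s
    rt_width: float  # Gaussian sigma, s
    amplitude: float  # a.u. at peak apex for a unit-abundance ion
    spectrum: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.rt_width <= 0:
            raise ValidationError("rt_width must be > 0")
        if any(ab <= 0 for _, ab in self.spectrum) or not self.spectrum:
            raise ValidationError("abundances must be positive and non-empty")


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for the simulator.

    Defaults describe a short UHPLC-like segment: 120 scans at 1 s intervals,
    five lipid-like components of 4–8 s peak width, m/z jitter sd 0.01 Da/e
    (well inside a 0.05 Da/e tolerance), a sparse noise floor and no scan
    dropout.  ``group_effect`` maps component index -> amplitude multiplier
    applied to exposed-group runs.
    """

    n_scans: int = 120
    scan_interval: float = 1.0
    components: tuple[SimComponent, ...] = ()
    mz_jitter_sd: float = 0.01
    baseline_rate: float = 5.0  # expected noise points per scan
    baseline_scale: float = 100.0  # exponential intensity scale, a.u.
    background_ions: int = 0  # persistent solvent/contaminant channels
    background_intensity_range: tuple[float, float] = (20.0, 2000.0)
    background_cv: float = 0.2  # scan-to-scan fluctuation of background ions
    # fraction of background ions carrying a companion channel a fraction of
    # a dalton away (adducts/in-source fragments); such pairs are resolved at
    # a tight mass tolerance but collapse at a loose one
    background_pair_fraction: float = 0.25
    mz_range: tuple[float, float] = (100.0, 1000.0)
    dropout_prob: float = 0.0
    detection_floor: float = 1.0  # points below this intensity are dropped
    amount_cv: float = 0.05  # lognormal sd of per-run component amounts
    group_effect: tuple[tuple[int, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scans < 1 or self.scan_interval <= 0:
            raise ValidationError("need n_scans >= 1 and scan_interval > 0")
        if self.mz_jitter_sd < 0 or self.baseline_rate < 0:
            raise ValidationError("jitter sd and baseline rate must be >= 0")
        if not 0 <= self.dropout_prob < 1:
            raise ValidationError("dropout_prob must be in [0, 1)")
        if self.amount_cv < 0:
            raise ValidationError("amount_cv must be >= 0")

    def times(self) -> np.ndarray:
        return self.scan_interval * (1.0 + np.arange(self.n_scans))

    def multiplier(self, component: int, group: str) -> float:
        if group == "exposed":
            for idx, mult in self.group_effect:
                if idx == component:
                    return mult
        return 1.0


@dataclass
class SimTruth:
    """Ground truth for one or more simulated runs."""

    spectra: list[np.ndarray]  # per component, (ions, 2) array of (mz, abund)
    amounts: dict[str, np.ndarray] = field(default_factory=dict)  # run -> per-comp amount
    profiles: dict[str, np.ndarray] = field(default_factory=dict)  # run -> scans x comps
    groups: dict[str, str] = field(default_factory=dict)

    def fold_change(self, component: int) -> float:
        """True exposed/control ratio of total injected amount."""
        ctrl = [a[component] for r, a in self.amounts.items() if self.groups[r] == "control"]
        expo = [a[component] for r, a in self.amounts.items() if self.groups[r] == "exposed"]
        return float(np.mean(expo) / np.mean(ctrl))


def default_spec(seed: int = 0, **overrides) -> SimSpec:
    """Five-component study conditions used throughout the test surface.

    Component amplitudes span an order of magnitude and ions sit far apart
    relative to the 0.05 Da/e tolerance; components 1 and 3 carry isotope-like
    satellites so one resolved component can bundle several ROIs.
    """
    components = (
        SimComponent(30.0, 5.0, 5.0e4, ((372.3105, 1.0),)),
        SimComponent(45.0, 6.0, 2.0e4, ((524.3716, 1.0), (525.3749, 0.35))),
        SimComponent(60.0, 4.0, 8.0e4, ((703.5740, 1.0),)),
        SimComponent(75.0, 7.0, 1.2e4, ((872.7702, 1.0), (873.7735, 0.55))),
        SimComponent(95.0, 8.0, 3.5e4, ((902.8171, 1.0),)),
    )
    kwargs = dict(components=components, seed=seed)
    kwargs.update(overrides)
    return SimSpec(**kwargs)


def _elution(spec: SimSpec, comp: SimComponent, times: np.ndarray) -> np.ndarray:
    z = (times - comp.rt_center) / comp.rt_width
    return comp.amplitude * np.exp(-0.5 * z * z)


def simulate_run(
    spec: SimSpec,
    sample_id: str = "sim",
    group: str = "control",
    rng: np.random.Generator | None = None,
) -> tuple[ScanList, SimTruth]:
    """Simulate one centroided run; deterministic given ``spec.seed``.

    ``group="exposed"`` applies the spec's per-component multipliers.  A
    shared ``rng`` may be passed to draw several runs from one stream (used
    by :func:`simulate_study`).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    times = spec.times()
    n_comp = len(spec.components)
    # background ion positions/means are instrument properties: drawn from
    # the spec seed so every replicate of a study sees the same channels
    if spec.background_ions:
        bg_rng = np.random.default_rng(spec.seed + 10_000)
        bg_mz = bg_rng.uniform(*spec.mz_range, size=spec.background_ions)
        lo, hi = spec.background_intensity_range
        bg_mean = np.exp(bg_rng.uniform(np.log(lo), np.log(hi),
                                        size=spec.background_ions))
        paired = bg_rng.uniform(size=spec.background_ions) < spec.background_pair_fraction
        if paired.any():
            comp_mz = bg_mz[paired] + bg_rng.uniform(0.1, 0.45, size=paired.sum())
            comp_mean = np.exp(bg_rng.uniform(np.log(lo), np.log(hi),
                                              size=paired.sum()))
            bg_mz = np.concatenate([bg_mz, comp_mz])
            bg_mean = np.concatenate([bg_mean, comp_mean])
        order = np.argsort(bg_mz)
        bg_mz, bg_mean = bg_mz[order], bg_mean[order]
    else:
        bg_mz = np.zeros(0)
        bg_mean = np.zeros(0)
    profiles = np.zeros((spec.n_scans, n_comp))
    scans: list[tuple[np.ndarray, np.ndarray]] = []
    mults = np.array([spec.multiplier(c, group) for c in range(n_comp)])
    if spec.amount_cv > 0 and n_comp:
        # replicate-to-replicate biological variability of injected amounts
        mults = mults * rng.lognormal(0.0, spec.amount_cv, size=n_comp)
    for c, comp in enumerate(spec.components):
        profiles[:, c] = mults[c] * _elution(spec, comp, times)

    for i in range(spec.n_scans):
        mzs: list[float] = []
        intens: list[float] = []
        dropped = spec.dropout_prob > 0 and rng.uniform() < spec.dropout_prob
        if not dropped:
            for c, comp in enumerate(spec.components):
                for ion_mz, abund in comp.spectrum:
                    inten = profiles[i, c] * abund
                    if inten <= spec.detection_floor:
                        continue
                    jitter = rng.normal(0.0, spec.mz_jitter_sd) if spec.mz_jitter_sd else 0.0
                    mzs.append(ion_mz + jitter)
                    intens.append(inten)
            for b in range(len(bg_mz)):
                inten = bg_mean[b] * (
                    rng.lognormal(0.0, spec.background_cv)
                    if spec.background_cv else 1.0
                )
                if inten <= spec.detection_floor:
                    continue
                jitter = rng.normal(0.0, spec.mz_jitter_sd) if spec.mz_jitter_sd else 0.0
                mzs.append(bg_mz[b] + jitter)
                intens.append(inten)
            n_noise = rng.poisson(spec.baseline_rate) if spec.baseline_rate else 0
            if n_noise:
                mzs.extend(rng.uniform(*spec.mz_range, size=n_noise))
                intens.extend(rng.exponential(spec.baseline_scale, size=n_noise))
        mz_arr = np.asarray(mzs, dtype=float)
        in_arr = np.asarray(intens, dtype=float)
        order = np.argsort(mz_arr, kind="stable")
        scans.append((mz_arr[order], in_arr[order]))

    run = ScanList(sample_id=sample_id, times=times, scans=scans)
    truth = SimTruth(
        spectra=[np.asarray(c.spectrum, dtype=float) for c in spec.components],
        amounts={sample_id: profiles.sum(axis=0)},
        profiles={sample_id: profiles},
        groups={sample_id: group},
    )
    return run, truth


def simulate_study(
    spec: SimSpec, n_control: int = 3, n_exposed: int = 3
) -> tuple[list[ScanList], SimTruth]:
    """Simulate a control-vs-exposed study (default 3 + 3 replicates).

    All runs are drawn from one seeded stream, so replicates differ in their
    noise realizations while sharing the study conditions; exposed runs get
    the spec's per-component amplitude multipliers.
    """
    if n_control < 1 or n_exposed < 1:
        raise ValidationError("need at least one run per group")
    rng = np.random.default_rng(spec.seed)
    runs: list[ScanList] = []
    truth = SimTruth(spectra=[np.asarray(c.spectrum, float) for c in spec.components])
    for k in range(n_control):
        run, t = simulate_run(spec, f"control{k + 1}", "control", rng)
        runs.append(run)
        truth.amounts.update(t.amounts)
        truth.profiles.update(t.profiles)
        truth.groups.update(t.groups)
    for k in range(n_exposed):
        run, t = simulate_run(spec, f"exposed{k + 1}", "exposed", rng)
        runs.append(run)
        truth.amounts.update(t.amounts)
        truth.profiles.update(t.profiles)
        truth.groups.update(t.groups)
    return runs, truth
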
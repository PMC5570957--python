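"""Virtual instrument: seeded generation of synthetic imaging and screening data.

This module stands in for the microfluidic imaging platform.  It produces,
with known ground truth, everything the analysis layers consume:

* ROI-level donor/acceptor intensity traces (:func:`simulate_trace`),
* full dual-channel z-stacks and recordings for one trapped worm
  (:func:`simulate_worm_session`),
* plate-scale cohorts of per-worm records with compound effects and QC
  classes (:func:`simulate_screen`),
* an on-disk plate dataset of TIFF stacks + sidecars for end-to-end runs
  (:func:`simulate_plate_to_dir`).

Everything is driven by a ``numpy.random.Generator``; identical seeds give
bit-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import ResponseKinetics, ideal_peak_pct, ideal_ratio
from .scene import BleachModel, NoiseConfig, SceneParams, render_frame
from .stacks import ChannelStack

__all__ = [
    "ProtocolTiming",
    "WormTruth",
    "QCRates",
    "simulate_trace",
    "simulate_zstack",
    "simulate_worm_session",
    "default_z_plan",
    "simulate_screen",
    "simulate_aging_cohorts",
    "simulate_plate_to_dir",
    "draw_peak_cohort",
    "unit_metrics",
    "demo_plate",
]


@dataclass(frozen=True)
class ProtocolTiming:
    """Per-worm protocol phases, in seconds.

    Defaults follow a 100 s/worm cycle: 5 s loading, 40 s pre-stimulation
    exposure (to settle the light-evoked baseline), 50 s stimulation and
    recording with a 30 s stimulus pulse, 5 s unloading.  The recording
    clock starts at the beginning of the pre-stimulation phase, so stimulus
    onset is at ``t = prestim_s``.
    """

    load_s: float = 5.0
    prestim_s: float = 40.0
    record_s: float = 50.0
    unload_s: float = 5.0
    stim_pulse_s: float = 30.0
    frame_interval_s: float = 0.5

    def __post_init__(self) -> None:
        for name in ("load_s", "prestim_s", "record_s", "unload_s", "stim_pulse_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame interval must be positive")
        if self.stim_pulse_s > self.record_s:
            raise ValueError("stimulus window must lie inside the recording window")

    @property
    def t_on(self) -> float:
        return self.prestim_s

    @property
    def t_off(self) -> float:
        return self.prestim_s + self.stim_pulse_s

    @property
    def duration_s(self) -> float:
        return self.prestim_s + self.record_s

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s / self.frame_interval_s))

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def kinetics(self, **kwargs) -> ResponseKinetics:
        """Kinetics aligned to this protocol's stimulus window."""
        return ResponseKinetics(t_on=self.t_on, t_off=self.t_off, **kwargs)


@dataclass
class WormTruth:
    """Ground truth recorded alongside every simulated worm."""

    worm_id: str
    well: str = ""
    r0: float = 1.5
    amplitude: float = 0.3
    tau_rise: float = 5.0
    tau_decay: float = 8.0
    neuron_x: float = np.nan
    neuron_y: float = np.nan
    z_true_um: float = np.nan
    orientation: str = "head_first"
    viability: str = "alive"
    expression: str = "normal"
    qc_class: str = "analyzed"
    lambda_donor: float = 0.0
    lambda_acceptor: float = 0.0
    true_peak_pct: float = np.nan

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "WormTruth":
        return cls(**d)


@dataclass(frozen=True)
class QCRates:
    """Per-worm probabilities of the discard classes.

    Defaults total 0.30, emulating the observed ~30% of worms discarded for
    tail entry, abnormal brightness, or death.
    """

    tail_entry: float = 0.12
    too_dim: float = 0.08
    too_bright: float = 0.05
    dead: float = 0.05

    def __post_init__(self) -> None:
        total = self.tail_entry + self.too_dim + self.too_bright + self.dead
        if not 0.0 <= total <= 1.0:
            raise ValueError("QC class rates must sum to at most 1")

    @property
    def total(self) -> float:
        return self.tail_entry + self.too_dim + self.too_bright + self.dead

    def draw(self, rng: np.random.Generator) -> str:
        u = rng.random()
        for name in ("tail_entry", "too_dim", "too_bright", "dead"):
            p = getattr(self, name)
            if u < p:
                return name
            u -= p
        return "analyzed"


NO_QC = QCRates(0.0, 0.0, 0.0, 0.0)


def simulate_trace(
    kinetics: ResponseKinetics,
    bleach: BleachModel,
    timing: ProtocolTiming,
    base_intensity: float = 1000.0,
    noise_rel: float = 0.02,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROI-level donor/acceptor intensity pair for one transient.

    The total fluorescence ``base_intensity`` is partitioned so that
    acceptor/donor equals the ideal ratio before noise, each channel then
    decays with its own bleach rate:

        donor(t)    = base * exp(-lambda_d t) / (1 + R(t))
        acceptor(t) = base * R(t) * exp(-lambda_a t) / (1 + R(t))

    ``noise_rel`` is the per-sample Gaussian noise sd relative to the
    expected intensity (0 disables noise; the default 0.02 gives a
    ratio-trace noise of ~2.8% per frame, i.e. a trace SNR of ~10 at the
    default 30% response amplitude).

    Returns ``(t, donor, acceptor)``.
    """
    t = timing.times()
    r = ideal_ratio(kinetics, t)
    fd, fa = bleach.factors(t)
    donor = base_intensity * fd / (1.0 + r)
    acceptor = base_intensity * r * fa / (1.0 + r)
    if noise_rel > 0:
        if rng is None:
            raise ValueError("rng required when noise_rel > 0")
        donor = donor + rng.normal(0.0, noise_rel * donor)
        acceptor = acceptor + rng.normal(0.0, noise_rel * acceptor)
    return t, donor, acceptor


def default_z_plan(n_planes: int = 21, z_range_um: tuple[float, float] = (0.0, 100.0)) -> np.ndarray:
    """Evenly spaced focus sweep covering the z range (default 21 planes over 0-100 um)."""
    if n_planes < 2:
        raise ValueError("z plan needs at least 2 planes")
    return np.linspace(z_range_um[0], z_range_um[1], n_planes)


def simulate_zstack(
    scene: SceneParams,
    r0: float = 1.5,
    z_plan: np.ndarray | None = None,
    noise: NoiseConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ChannelStack:
    """Render a focus sweep of one scene at the resting ratio (t = 0 bleach state)."""
    if z_plan is None:
        z_plan = default_z_plan(z_range_um=scene.z_range_um)
    z_plan = np.asarray(z_plan, dtype=float)
    part0 = (1.0 / (1.0 + r0), r0 / (1.0 + r0))
    frames_d, frames_a = [], []
    for z in z_plan:
        d, a = render_frame(scene, z - scene.z_true_um, (1.0, 1.0), part0, noise, rng)
        frames_d.append(d)
        frames_a.append(a)
    return ChannelStack(
        np.stack(frames_d), np.stack(frames_a), axis="z",
        pixel_size_um=scene.pixel_size_um, z_values_um=z_plan,
    )


def simulate_worm_session(
    scene: SceneParams,
    kinetics: ResponseKinetics,
    bleach: BleachModel,
    timing: ProtocolTiming,
    z_plan: np.ndarray | None = None,
    noise: NoiseConfig | None = None,
    rng: np.random.Generator | None = None,
    worm_id: str = "worm",
) -> tuple[ChannelStack, ChannelStack, WormTruth]:
    """One load-focus-stimulate-record cycle for a single worm.

    Returns the autofocus z stack (taken at the t = 0 bleach state), the
    stimulus recording time series (taken at the neuron's focal plane), and
    the worm's ground truth.  Dead worms respond with amplitude 0.
    """
    if z_plan is None:
        z_plan = default_z_plan(z_range_um=scene.z_range_um)
    z_plan = np.asarray(z_plan, dtype=float)
    if scene.orientation == "tail_first" and scene.neuron_x < scene.width / 2:
        # by contract the neuron of a tail-first worm sits in the tail-side half
        scene = scene.flipped()
    if scene.viability == "dead":
        kinetics = kinetics.with_amplitude(0.0)
    if noise is not None and noise.enabled and rng is None:
        raise ValueError("rng required when noise is enabled")

    zstack = simulate_zstack(scene, kinetics.r0, z_plan, noise, rng)

    t = timing.times()
    r = ideal_ratio(kinetics, t)
    fd, fa = bleach.factors(t)
    tframes_d, tframes_a = [], []
    for i in range(t.size):
        part = (1.0 / (1.0 + r[i]), r[i] / (1.0 + r[i]))
        d, a = render_frame(scene, 0.0, (fd[i], fa[i]), part, noise, rng)
        tframes_d.append(d)
        tframes_a.append(a)
    series = ChannelStack(
        np.stack(tframes_d), np.stack(tframes_a), axis="time",
        pixel_size_um=scene.pixel_size_um, frame_interval_s=timing.frame_interval_s,
    )

    truth = WormTruth(
        worm_id=worm_id,
        r0=kinetics.r0,
        amplitude=kinetics.amplitude,
        tau_rise=kinetics.tau_rise,
        tau_decay=kinetics.tau_decay,
        neuron_x=scene.neuron_x,
        neuron_y=scene.neuron_y,
        z_true_um=scene.z_true_um,
        orientation=scene.orientation,
        viability=scene.viability,
        expression=scene.expression,
        lambda_donor=bleach.lambda_donor,
        lambda_acceptor=bleach.lambda_acceptor,
        true_peak_pct=ideal_peak_pct(kinetics),
    )
    return zstack, series, truth


def _draw_amplitude(mean_a: float, cv: float, rng: np.random.Generator) -> float:
    if cv == 0:
        return mean_a
    return float(max(0.0, rng.normal(mean_a, cv * mean_a)))


def simulate_screen(
    layout,
    effects: dict[str, float] | None = None,
    worms_per_well: int = 15,
    base_kinetics: ResponseKinetics | None = None,
    cv: float = 0.3,
    qc_rates: QCRates | None = None,
    age_day: int = 12,
    timing: ProtocolTiming | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-worm records for a plate-scale screen, with full ground truth.

    Control wells draw the response amplitude from the base distribution
    (mean ``base_kinetics.amplitude``, between-worm coefficient of variation
    ``cv``); a compound well with effect multiplier ``e`` draws with mean
    scaled by ``(1 + e)``.  Each worm is assigned a QC class at the
    configured rates; worms that are not ``analyzed`` carry no metrics.

    Returned frame columns include both ground truth (``amplitude_true``,
    ``qc``, ``effect_true``) and the measured quantities the analysis layer
    consumes (``peak_pct``, ``slope_pct_s``).
    """
    from .fret import metrics_from_ideal  # local import: avoids a module cycle

    if rng is None:
        raise ValueError("simulate_screen requires an rng (seeded reproducibility)")
    timing = timing or ProtocolTiming()
    base_kinetics = base_kinetics or timing.kinetics()
    effects = effects or {}
    qc_rates = qc_rates if qc_rates is not None else QCRates()
    for well, e in effects.items():
        if e < -1:
            raise ValueError(f"effect multiplier {e} at {well} would give negative amplitude")
    if worms_per_well < 1:
        raise ValueError("worms_per_well must be >= 1")

    # peak and slope are both linear in amplitude, so measure them once at A=1
    unit = metrics_from_ideal(base_kinetics.with_amplitude(1.0), timing)
    rows = []
    for well in layout.wells():
        role = layout.role(well)
        if role == "medium_only":
            continue
        eff = float(effects.get(well, 0.0)) if role == "compound" else 0.0
        mean_a = base_kinetics.amplitude * (1.0 + eff)
        for i in range(worms_per_well):
            qc = qc_rates.draw(rng)
            a = _draw_amplitude(mean_a, cv, rng)
            if qc == "dead":
                a = 0.0
            analyzed = qc == "analyzed"
            rows.append(
                {
                    "worm_id": f"{well}_w{i:02d}",
                    "well": well,
                    "role": role,
                    "compound": layout.compound(well) if role == "compound" else "",
                    "concentration_uM": layout.concentration(well) if role == "compound" else 0.0,
                    "age_day": age_day,
                    "qc": qc,
                    "amplitude_true": a,
                    "effect_true": eff,
                    "peak_pct": unit.peak_pct * a if analyzed else np.nan,
                    "slope_pct_s": unit.slope_pct_s * a if analyzed else np.nan,
                }
            )
    return pd.DataFrame(rows)


def simulate_aging_cohorts(
    day_mean_amplitude: dict[int, float],
    n_per_day: int = 40,
    cv: float = 0.3,
    base_kinetics: ResponseKinetics | None = None,
    timing: ProtocolTiming | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-worm peak/slope records across days of adulthood.

    ``day_mean_amplitude`` maps day -> mean fractional amplitude, emulating
    e.g. a rise-then-fall trajectory of neuronal responsiveness with age.
    """
    from .fret import metrics_from_ideal

    if rng is None:
        raise ValueError("simulate_aging_cohorts requires an rng")
    timing = timing or ProtocolTiming()
    base_kinetics = base_kinetics or timing.kinetics()
    unit = metrics_from_ideal(base_kinetics.with_amplitude(1.0), timing)
    rows = []
    for day, mean_a in sorted(day_mean_amplitude.items()):
        for i in range(n_per_day):
            a = _draw_amplitude(mean_a, cv, rng)
            rows.append(
                {
                    "worm_id": f"d{day:02d}_w{i:03d}",
                    "age_day": day,
                    "qc": "analyzed",
                    "amplitude_true": a,
                    "peak_pct": unit.peak_pct * a,
                    "slope_pct_s": unit.slope_pct_s * a,
                }
            )
    return pd.DataFrame(rows)


_UNIT_CACHE: dict[tuple, tuple[float, float]] = {}


def unit_metrics(timing: ProtocolTiming | None = None, base_kinetics: ResponseKinetics | None = None) -> tuple[float, float]:
    """Peak (%) and slope (%/s) the quantification stage measures per unit amplitude.

    Both metrics are linear in the response amplitude, so cohorts can be
    drawn at the metric level by scaling these factors; cached per
    (timing, kinetics) configuration.
    """
    from .fret import metrics_from_ideal

    timing = timing or ProtocolTiming()
    base_kinetics = base_kinetics or timing.kinetics()
    key = (
        timing.prestim_s, timing.record_s, timing.stim_pulse_s, timing.frame_interval_s,
        base_kinetics.r0, base_kinetics.tau_rise, base_kinetics.tau_decay,
    )
    if key not in _UNIT_CACHE:
        m = metrics_from_ideal(base_kinetics.with_amplitude(1.0), timing)
        _UNIT_CACHE[key] = (m.peak_pct, m.slope_pct_s)
    return _UNIT_CACHE[key]


def draw_peak_cohort(
    n: int,
    rng: np.random.Generator,
    mean_amplitude: float = 0.3,
    cv: float = 0.3,
    effect: float = 0.0,
    timing: ProtocolTiming | None = None,
    base_kinetics: ResponseKinetics | None = None,
) -> np.ndarray:
    """Per-worm transient peaks (%) for one well's analyzed cohort.

    The fast, metrics-level path of the generator: amplitudes are drawn
    from the between-worm distribution (mean scaled by ``1 + effect``) and
    mapped through the quantification stage's unit-amplitude peak.
    Distribution-identical to quantifying each worm's noise-free trace.
    """
    if effect < -1:
        raise ValueError("effect multiplier < -1 would give negative amplitudes")
    unit_peak, _ = unit_metrics(timing, base_kinetics)
    mean_a = mean_amplitude * (1.0 + effect)
    if cv == 0:
        amps = np.full(n, mean_a)
    else:
        amps = np.clip(rng.normal(mean_a, cv * mean_a, size=n), 0.0, None)
    return unit_peak * amps


def demo_plate() -> tuple["PlateLayout", dict[str, float]]:
    """A 12-well integration plate with known hit structure.

    Nine compound wells (two true positives at +60%, two true negatives at
    -50%, five nulls), two interleaved vehicle-control wells, one
    medium-only well.  Returns ``(layout, effects)``.
    """
    from .screening import PlateLayout

    roles = {"A1": "medium_only", "B11": "vehicle_control", "C11": "vehicle_control"}
    compounds = {}
    for i, col in enumerate(range(2, 11)):
        well = f"B{col}"
        roles[well] = "compound"
        compounds[well] = f"compound_{i:02d}"
    effects = {"B2": 0.6, "B6": 0.6, "B3": -0.5, "B8": -0.5}
    return PlateLayout(roles, compounds), effects


def simulate_plate_to_dir(
    layout,
    out_dir: str | Path,
    effects: dict[str, float] | None = None,
    worms_per_well: int = 8,
    base_kinetics: ResponseKinetics | None = None,
    cv: float = 0.15,
    qc_rates: QCRates | None = None,
    timing: ProtocolTiming | None = None,
    scene: SceneParams | None = None,
    bleach: BleachModel | None = None,
    noise: NoiseConfig | None = None,
    n_planes: int = 21,
    seed: int = 0,
    wells: list[str] | None = None,
) -> Path:
    """Write a full image-level plate dataset to disk.

    Layout: ``<out_dir>/<well>/<worm_id>/{zstack.tif, timeseries.tif,
    meta.json}`` plus ``template.tif``, ``layout.yaml`` and
    ``ground_truth.csv``/``.json`` at the root.  The per-worm metadata
    sidecar records the instrument's own observations, including viability
    (a dead worm is recognized on-chip and discarded before recording).

    ``wells`` restricts generation to a subset of the layout's wells.
    """
    from . import io as fio
    from .scene import make_template

    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timing = timing or ProtocolTiming()
    base_kinetics = base_kinetics or timing.kinetics()
    scene = scene or SceneParams()
    bleach = bleach or BleachModel()
    noise = noise if noise is not None else NoiseConfig()
    qc_rates = qc_rates if qc_rates is not None else QCRates()
    effects = effects or {}
    z_plan = default_z_plan(n_planes, scene.z_range_um)

    fio.write_template(out / "template.tif", make_template(scene.sigma0_px))
    layout.to_yaml(out / "layout.yaml")

    truths = []
    target_wells = wells if wells is not None else [
        w for w in layout.wells() if layout.role(w) != "medium_only"
    ]
    for well in target_wells:
        role = layout.role(well)
        eff = float(effects.get(well, 0.0)) if role == "compound" else 0.0
        for i in range(worms_per_well):
            worm_id = f"{well}_w{i:02d}"
            qc = qc_rates.draw(rng)
            a = _draw_amplitude(base_kinetics.amplitude * (1.0 + eff), cv, rng)
            wscene = replace(
                scene,
                neuron_x=scene.neuron_x + rng.uniform(-4, 4),
                neuron_y=scene.neuron_y + rng.uniform(-4, 4),
                z_true_um=rng.uniform(30.0, 70.0),
                orientation="tail_first" if qc == "tail_entry" else "head_first",
                viability="dead" if qc == "dead" else "alive",
                expression={"too_dim": "dim", "too_bright": "bright"}.get(qc, "normal"),
            )
            kin = base_kinetics.with_amplitude(a)
            zstack, series, truth = simulate_worm_session(
                wscene, kin, bleach, timing, z_plan, noise, rng, worm_id=worm_id
            )
            truth.well = well
            truth.qc_class = qc
            wdir = out / well / worm_id
            fio.write_stack(wdir / "zstack.tif", zstack, seed=seed)
            fio.write_stack(
                wdir / "timeseries.tif", series, seed=seed,
                extra_meta={"viability": wscene.viability, "timing": asdict(timing)},
            )
            truths.append(truth)

    truth_df = pd.DataFrame([t.to_dict() for t in truths])
    truth_df.to_csv(out / "ground_truth.csv", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "seed": seed,
                "effects": effects,
                "worms_per_well": worms_per_well,
                "cv": cv,
                "worms": [t.to_dict() for t in truths],
            },
            fh,
            indent=1,
        )
    return out
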
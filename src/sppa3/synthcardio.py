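"""Synthetic cohort generator: beat-aligned BBI/SBP/DBP and breath-aligned RESP.

Each subject is a 30-min recording built from a deliberately simple model —
AR(1) fluctuations per signal, a sinusoidal respiratory modulation of the
beat-to-beat interval (respiratory sinus arrhythmia), and a lagged linear
baroreflex-like coupling of the interval to the previous beat's systolic
pressure:

    BBI_n = μ + a·(BBI_{n−1} − μ) + g_rsa·sin(2π·φ_n)
              + g_brs·(SBP_{n−1} − μ_SBP) + ε_n

where φ_n is the phase of the ongoing breath at beat n.  Beat times
accumulate from the generated intervals; respiratory cycle lengths follow
their own AR(1) process on the breath grid.  The point is controllable
coupling structure and group differences for the box-model pipeline to
find, not physiological fidelity.

Group presets mirror the study design qualitatively: five groups (healthy
non-pregnant controls, healthy pregnant, chronic hypertension,
pregnancy-induced hypertension, pre-eclampsia) with sizes 10/66/13/14/19,
rising blood pressure across the hypertensive groups, and a pre-eclampsia
preset with raised mean interval and systolic pressure, short breathing
cycles, and weakened respiratory/baroreflex coupling gains.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .signals import BeatSeries, SignalKind, write_beat_series

__all__ = [
    "SubjectParams",
    "GroupPreset",
    "SubjectRecord",
    "generate_subject",
    "generate_cohort",
    "default_presets",
    "write_cohort",
    "read_manifest",
]


@dataclass(frozen=True)
class SubjectParams:
    """Generator parameters of one synthetic subject.

    ``sd_*`` is the marginal SD of the AR(1) component of the signal (the
    innovation SD is scaled by sqrt(1−ar²)); the RSA and baroreflex terms
    add variance on top of ``sd_bbi``.  Gains: ``rsa_gain`` in ms of
    peak respiratory modulation, ``baroreflex_gain`` in ms per mmHg of
    previous-beat systolic deviation.
    """

    mean_bbi: float = 750.0  # ms
    sd_bbi: float = 45.0
    mean_sbp: float = 120.0  # mmHg
    sd_sbp: float = 8.0
    mean_dbp: float = 75.0  # mmHg
    sd_dbp: float = 6.0
    mean_resp: float = 3.5  # s, breathing cycle length
    sd_resp: float = 0.35
    rsa_gain: float = 12.0  # ms
    baroreflex_gain: float = 0.7  # ms/mmHg
    ar_bbi: float = 0.8
    ar_sbp: float = 0.8
    ar_dbp: float = 0.8
    ar_resp: float = 0.6
    duration_s: float = 1800.0  # 30-min recording
    seed: int = 0

    def validate(self) -> None:
        if self.mean_bbi <= 0 or self.mean_resp <= 0:
            raise ValueError("mean BBI and RESP cycle length must be positive")
        if self.mean_sbp <= self.mean_dbp:
            raise ValueError("mean SBP must exceed mean DBP (pulse pressure > 0)")
        if min(self.sd_bbi, self.sd_sbp, self.sd_dbp, self.sd_resp) <= 0:
            raise ValueError("all SDs must be positive")
        for a in (self.ar_bbi, self.ar_sbp, self.ar_dbp, self.ar_resp):
            if not abs(a) < 1:
                raise ValueError("AR coefficients must satisfy |a| < 1")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class GroupPreset:
    label: str
    params: SubjectParams
    n_subjects: int

    def __post_init__(self) -> None:
        from .groupstats import GROUP_LABELS

        if self.label not in GROUP_LABELS:
            raise ValueError(f"unknown group label {self.label!r}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    label: str
    series: dict[SignalKind, BeatSeries]


def _ar1(rng: np.random.Generator, n: int, sd: float, ar: float) -> np.ndarray:
    """Zero-mean AR(1) with marginal SD ``sd``, started at stationarity."""
    e = rng.normal(0.0, sd * math.sqrt(1.0 - ar * ar), n)
    e[0] = rng.normal(0.0, sd)
    return lfilter([1.0], [1.0, -ar], e)


def generate_subject(params: SubjectParams) -> dict[SignalKind, BeatSeries]:
    """Simulate one subject; fully reproducible from ``params.seed``."""
    params.validate()
    rng = np.random.default_rng(params.seed)

    # breath grid: AR(1) cycle lengths, onset times accumulate
    n_breaths = int(params.duration_s / params.mean_resp * 2) + 20
    cycles = params.mean_resp + _ar1(rng, n_breaths, params.sd_resp, params.ar_resp)
    cycles = np.clip(cycles, 0.2, None)
    breath_times = np.concatenate([[0.0], np.cumsum(cycles[:-1])])

    max_beats = int(params.duration_s * 1000.0 / max(params.mean_bbi * 0.5, 250.0)) + 64
    sbp = params.mean_sbp + _ar1(rng, max_beats, params.sd_sbp, params.ar_sbp)
    dbp = params.mean_dbp + _ar1(rng, max_beats, params.sd_dbp, params.ar_dbp)
    dbp = np.minimum(dbp, sbp - 1.0)  # pulse pressure stays positive
    noise = rng.normal(
        0.0, params.sd_bbi * math.sqrt(1.0 - params.ar_bbi**2), max_beats
    )

    times = np.empty(max_beats)
    bbi = np.empty(max_beats)
    t = 0.0
    prev = params.mean_bbi
    prev_sbp = params.mean_sbp
    two_pi = 2.0 * math.pi
    i = 0
    while t < params.duration_s and i < max_beats:
        j = np.searchsorted(breath_times, t, side="right") - 1
        phase = (t - breath_times[j]) / cycles[j]
        b = (
            params.mean_bbi
            + params.ar_bbi * (prev - params.mean_bbi)
            + params.rsa_gain * math.sin(two_pi * phase)
            + params.baroreflex_gain * (prev_sbp - params.mean_sbp)
            + noise[i]
        )
        b = max(b, 250.0)  # physical floor on the interbeat interval
        times[i] = t
        bbi[i] = b
        t += b / 1000.0
        prev = b
        prev_sbp = sbp[i]
        i += 1

    times = times[:i]
    keep_breaths = breath_times <= times[-1]
    return {
        SignalKind.BBI: BeatSeries(SignalKind.BBI, times, bbi[:i]),
        SignalKind.SBP: BeatSeries(SignalKind.SBP, times, np.clip(sbp[:i], 1.0, None)),
        SignalKind.DBP: BeatSeries(SignalKind.DBP, times, np.clip(dbp[:i], 0.5, None)),
        SignalKind.RESP: BeatSeries(
            SignalKind.RESP, breath_times[keep_breaths], cycles[keep_breaths]
        ),
    }


#: Group templates: qualitative severity gradient in blood pressure, a
#: pre-eclampsia preset with raised mean BBI/SBP, short breathing cycles and
#: weakened coupling gains, and the study's group sizes 10/66/13/14/19.
_GROUP_TEMPLATES: dict[str, tuple[SubjectParams, int]] = {
    "CON": (
        SubjectParams(mean_bbi=850, sd_bbi=55, mean_sbp=112, sd_sbp=7, mean_dbp=70,
                      sd_dbp=5, mean_resp=3.8, sd_resp=0.40, rsa_gain=18,
                      baroreflex_gain=0.9),
        10,
    ),
    "PREG": (
        SubjectParams(mean_bbi=700, sd_bbi=45, mean_sbp=115, sd_sbp=8, mean_dbp=72,
                      sd_dbp=6, mean_resp=3.4, sd_resp=0.35, rsa_gain=12,
                      baroreflex_gain=0.7),
        66,
    ),
    "CH": (
        SubjectParams(mean_bbi=720, sd_bbi=45, mean_sbp=135, sd_sbp=10, mean_dbp=85,
                      sd_dbp=7, mean_resp=3.4, sd_resp=0.35, rsa_gain=10,
                      baroreflex_gain=0.5),
        13,
    ),
    "PIH": (
        SubjectParams(mean_bbi=715, sd_bbi=45, mean_sbp=140, sd_sbp=10, mean_dbp=88,
                      sd_dbp=7, mean_resp=3.4, sd_resp=0.35, rsa_gain=10,
                      baroreflex_gain=0.5),
        14,
    ),
    "PE": (
        SubjectParams(mean_bbi=780, sd_bbi=50, mean_sbp=150, sd_sbp=12, mean_dbp=95,
                      sd_dbp=8, mean_resp=2.7, sd_resp=0.30, rsa_gain=6,
                      baroreflex_gain=0.3),
        19,
    ),
}


def default_presets(
    scale: float = 1.0, duration_s: float = 1800.0
) -> list[GroupPreset]:
    """The five default group presets; sizes scaled with ceiling."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return [
        GroupPreset(
            label=label,
            params=replace(params, duration_s=duration_s),
            n_subjects=math.ceil(n * scale),
        )
        for label, (params, n) in _GROUP_TEMPLATES.items()
    ]


def generate_cohort(
    presets: list[GroupPreset] | tuple[GroupPreset, ...], seed: int
) -> list[SubjectRecord]:
    """Generate all subjects; per-subject seeds derive from the master seed."""
    labels = [p.label for p in presets]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate group labels in presets")
    total = sum(p.n_subjects for p in presets)
    children = np.random.SeedSequence(seed).spawn(total)
    records = []
    k = 0
    for preset in presets:
        for j in range(preset.n_subjects):
            sub_seed = int(children[k].generate_state(1)[0])
            k += 1
            params = replace(preset.params, seed=sub_seed)
            records.append(
                SubjectRecord(
                    subject_id=f"{preset.label}{j + 1:03d}",
                    label=preset.label,
                    series=generate_subject(params),
                )
            )
    return records


def write_cohort(
    records: list[SubjectRecord], outdir: str | Path, seed: int | None = None
) -> Path:
    """Per-subject signal CSVs plus a manifest JSON; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "subjects": []}
    for rec in records:
        subdir = outdir / rec.subject_id
        subdir.mkdir(exist_ok=True)
        files = {}
        for kind, series in rec.series.items():
            fname = f"{kind.value.lower()}.csv"
            write_beat_series(series, subdir / fname)
            files[kind.value] = f"{rec.subject_id}/{fname}"
        manifest["subjects"].append(
            {"id": rec.subject_id, "label": rec.label, "files": files}
        )
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
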
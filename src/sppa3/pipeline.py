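"""Orchestration helpers shared by the CLI, tests, and reproduction script.

Bridges the generator/feature/screening layers: given subject recordings
(in memory or on disk), build per-subject probability boxes for the
requested couplings and variants, collect them into cohort feature tables,
and run the screening / best-index workflow.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .boxmodel import ProbabilityBox, coarse_grain, multivariate_box
from .groupstats import CohortFeatures
from .signals import BeatSeries, SignalKind, align_signals
from .synthcardio import SubjectRecord
from .univariate import univariate_box

__all__ = [
    "COUPLINGS",
    "feature_set_name",
    "subject_box",
    "build_cohort_features",
    "screening_replicates",
]

#: The four multivariate couplings, in fixed axis order (X, Y, Z).
COUPLINGS: dict[str, tuple[SignalKind, SignalKind, SignalKind]] = {
    "BBI_DBP_RESP": (SignalKind.BBI, SignalKind.DBP, SignalKind.RESP),
    "BBI_SBP_DBP": (SignalKind.BBI, SignalKind.SBP, SignalKind.DBP),
    "BBI_SBP_RESP": (SignalKind.BBI, SignalKind.SBP, SignalKind.RESP),
    "SBP_DBP_RESP": (SignalKind.SBP, SignalKind.DBP, SignalKind.RESP),
}


def feature_set_name(
    coupling: str, mode: str, rotate: bool, n_cells: int
) -> str:
    """E.g. 'BBI_SBP_RESP-adapted-norot-12' or 'uniSBP-predefined-rot-6'."""
    return f"{coupling}-{mode}-{'rot' if rotate else 'norot'}-{n_cells}"


def subject_box(
    series: dict[SignalKind, BeatSeries],
    coupling: str,
    mode: str = "adapted",
    rotate: bool = False,
    n_cells: int = 12,
    align_method: str = "previous_event",
) -> ProbabilityBox:
    """One subject's probability box for a coupling or a univariate signal.

    ``coupling`` is either a key of :data:`COUPLINGS` or ``"uni<KIND>"``
    (e.g. ``"uniSBP"``) for the lag-embedded univariate analysis.  The
    coarse (6-cell) model is derived by coarse-graining the fine box.
    """
    if coupling.startswith("uni"):
        kind = SignalKind(coupling[3:])
        box = univariate_box(series[kind], rotate=rotate, mode=mode, n_cells=12)
        if n_cells == 6:
            box = coarse_grain(box)
        return box
    kinds = COUPLINGS[coupling]
    recording = align_signals([series[k] for k in kinds], method=align_method)
    return multivariate_box(recording, mode=mode, rotate=rotate, n_cells=n_cells)


def build_cohort_features(
    records: list[SubjectRecord],
    couplings: list[str],
    mode: str = "adapted",
    rotate: bool = False,
    n_cells: int = 12,
    align_method: str = "previous_event",
) -> CohortFeatures:
    """Cohort feature tables (subjects × cubelet labels) per coupling."""
    cohort = CohortFeatures(
        subjects=[r.subject_id for r in records],
        labels=[r.label for r in records],
    )
    for coupling in couplings:
        rows = []
        for rec in records:
            box = subject_box(
                rec.series, coupling, mode=mode, rotate=rotate,
                n_cells=n_cells, align_method=align_method,
            )
            rows.append(box.to_series())
        frame = pd.DataFrame(rows, index=cohort.subjects)
        variant = "univariate" if coupling.startswith("uni") else "multivariate"
        cohort.add_table(
            feature_set_name(coupling, mode, rotate, n_cells), frame, variant
        )
    return cohort


def screening_replicates(
    presets,
    n_replicates: int,
    seed: int,
    test_id: str = "IX",
    coupling: str = "BBI_SBP_RESP",
    mode: str = "predefined",
    rotate: bool = False,
    n_cells: int = 12,
):
    """Repeat cohort generation → features → screening; one result per replicate.

    Used for calibration (identical presets should yield chance-level
    detections) and power (differing presets should yield reproducible
    detections) experiments.  Replicate seeds derive from the master seed.
    """
    from .groupstats import ScreeningResult, group_test, screen_cubelets
    from .synthcardio import generate_cohort

    test = group_test(test_id)
    name = feature_set_name(coupling, mode, rotate, n_cells)
    results: list[ScreeningResult] = []
    rep_seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    for rs in rep_seeds:
        records = generate_cohort(presets, seed=int(rs.generate_state(1)[0]))
        cohort = build_cohort_features(
            records, [coupling], mode=mode, rotate=rotate, n_cells=n_cells
        )
        results.append(screen_cubelets(cohort, test, name))
    return results
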
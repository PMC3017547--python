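"""Beta-value computation and control-anchored range-scaling normalization.

beta = methylated / (methylated + unmethylated); per-probe normalization maps
the fully-unmethylated control mean to 0 and the fully-methylated control
mean to 1, with the half-methylated control kept aside as an internal QC
check expected to land near 0.5.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import (
    CONTROL_CLASSES,
    CONTROL_FULL_METHYL,
    CONTROL_HALF_METHYL,
    CONTROL_UNMETHYL,
    BetaMatrix,
    ControlProfile,
    SampleSheet,
    SignalMatrix,
)

DEFAULT_EPS_RANGE = 0.3


def compute_beta(signals: SignalMatrix, alpha: float = 0.0) -> BetaMatrix:
    """beta = M / (M + U + alpha); cells with a zero denominator are missing.

    ``alpha`` is an optional stabilizing pseudocount (0 reproduces the plain
    ratio; 100 is a common convention for raw intensities).
    """
    if alpha < 0:
        raise ValidationError("pseudocount alpha must be non-negative")
    meth = signals.methylated.to_numpy(dtype=float)
    unmeth = signals.unmethylated.to_numpy(dtype=float)
    denom = meth + unmeth + alpha
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, meth / denom, np.nan)
    return BetaMatrix(
        values=pd.DataFrame(beta, index=signals.probe_ids, columns=signals.sample_ids),
        normalized=False,
    )


def build_control_profile(
    beta: BetaMatrix, samples: SampleSheet, eps_range: float = DEFAULT_EPS_RANGE
) -> ControlProfile:
    """Per-probe anchor means over the control replicates.

    A probe is unusable when any anchor is missing or the full/zero anchors
    are closer than ``eps_range`` (the three-state call would be meaningless).
    """
    anchors = {}
    for cls, column in (
        (CONTROL_FULL_METHYL, "beta_full"),
        (CONTROL_UNMETHYL, "beta_zero"),
        (CONTROL_HALF_METHYL, "beta_half"),
    ):
        sample_ids = samples.samples_of_class(cls)
        if not sample_ids:
            raise ValidationError(f"no samples of control class {cls!r}")
        missing = [s for s in sample_ids if s not in beta.sample_ids]
        if missing:
            raise ValidationError(f"control samples absent from beta matrix: {missing}")
        anchors[column] = beta.values[sample_ids].mean(axis=1)

    frame = pd.DataFrame(anchors)
    frame["usable"] = (
        frame[["beta_full", "beta_zero", "beta_half"]].notna().all(axis=1)
        & ((frame["beta_full"] - frame["beta_zero"]) >= eps_range)
    )
    return ControlProfile(frame=frame, eps_range=eps_range)


def range_scale_normalize(beta: BetaMatrix, profile: ControlProfile) -> BetaMatrix:
    """Per-probe linear rescale: control-zero anchor -> 0, control-full -> 1.

    Values are clipped into [0, 1]; unusable probes become all-missing.
    Normalizing an already-normalized matrix is rejected.
    """
    if beta.normalized:
        raise ValidationError("matrix is already normalized; refusing to renormalize")
    if not beta.probe_ids.equals(profile.probe_ids):
        raise ValidationError("beta matrix and control profile cover different probes")

    zero = profile.frame["beta_zero"].to_numpy(dtype=float)[:, None]
    full = profile.frame["beta_full"].to_numpy(dtype=float)[:, None]
    usable = profile.frame["usable"].to_numpy(dtype=bool)[:, None]

    raw = beta.values.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (raw - zero) / (full - zero)
    scaled = np.clip(scaled, 0.0, 1.0)
    scaled = np.where(usable, scaled, np.nan)
    return BetaMatrix(
        values=pd.DataFrame(scaled, index=beta.probe_ids, columns=beta.sample_ids),
        normalized=True,
        anchors=profile.frame[["beta_full", "beta_zero", "beta_half", "usable"]].copy(),
    )


def control_qc(
    normalized: BetaMatrix,
    profile: ControlProfile,
    samples: SampleSheet,
    tol: float = 0.05,
) -> pd.DataFrame:
    """Flag probes whose normalized half-methylated control mean strays from 0.5.

    Returns a probe-indexed frame with ``half_mean`` and boolean ``flagged``.
    Probes with no usable normalized value are left unflagged.
    """
    if not normalized.normalized:
        raise ValidationError("control_qc requires a normalized beta matrix")
    half_samples = samples.samples_of_class(CONTROL_HALF_METHYL)
    if not half_samples:
        raise ValidationError("no half-methylated control samples in sheet")
    half_mean = normalized.values[half_samples].mean(axis=1)
    flagged = (half_mean - 0.5).abs() > tol
    flagged &= half_mean.notna()
    return pd.DataFrame({"half_mean": half_mean, "flagged": flagged})
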
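"""Headline-count reproduction on the deposited array series.

This path needs externally staged inputs (none ship with the package and
none can be fetched at run time):

``<data_dir>/GSE25538_series_matrix.txt``
    The deposited series-matrix export (beta values per probe/sample).
``<data_dir>/imprinted_annotation.tsv``
    User-supplied probe annotation flagging the 47 imprinted genes with
    parental directions — this mapping was never published with the study.
``<data_dir>/samples.tsv``
    Sample sheet assigning the deposited samples to classes/lines.

The state-call thresholds and the differential delta are calibration
parameters because the study does not report them.
"""

from __future__ import annotations

from pathlib import Path

from . import io
from .errors import ValidationError
from .groups import differential_imprinted, maternal_consistency
from .states import aggregate_replicates, call_states, tissue_partial_filter
from .types import CONTROL_CLASSES, CONVENTIONAL_ESC, PARTHENOTE_ESC, BetaMatrix


def available(data_dir: str | Path) -> bool:
    data_dir = Path(data_dir)
    return all(
        (data_dir / name).exists()
        for name in ("GSE25538_series_matrix.txt", "imprinted_annotation.tsv", "samples.tsv")
    )


def compute_real_data_targets(
    data_dir: str | Path,
    t_low: float = 0.3,
    t_high: float = 0.7,
    delta: float = 0.2,
    aggregation: str = "any_probe",
    normalize: bool = False,
) -> dict[str, dict[str, float | int]]:
    """Recompute the headline counts from staged real data.

    Deposited series matrices usually carry already-normalized beta values,
    so control-anchored normalization is off by default; pass
    ``normalize=True`` when control samples are present in the sheet.
    """
    data_dir = Path(data_dir)
    if not available(data_dir):
        raise ValidationError(f"real-data inputs not staged under {data_dir}")

    values = io.read_matrix(data_dir / "GSE25538_series_matrix.txt", dialect="geo_series_matrix")
    annotation = io.read_annotation(data_dir / "imprinted_annotation.tsv")
    samples = io.read_sample_sheet(data_dir / "samples.tsv")

    shared = [s for s in samples.sample_ids if s in values.columns]
    beta = BetaMatrix(values=values[shared].clip(0.0, 1.0), normalized=not normalize)
    if normalize:
        from .beta import build_control_profile, range_scale_normalize

        raw = BetaMatrix(values=beta.values, normalized=False)
        beta = range_scale_normalize(raw, build_control_profile(raw, samples))

    line_beta = aggregate_replicates(beta, samples)
    states = call_states(line_beta, t_low=t_low, t_high=t_high)

    sites0 = tissue_partial_filter(states, annotation, samples, d=0)
    sites1 = tissue_partial_filter(states, annotation, samples, d=1)
    n = sites0.n_sites

    parthenote = samples.lines_of_class(PARTHENOTE_ESC)
    report = maternal_consistency(sites0, states, annotation, parthenote)

    diff = differential_imprinted(
        line_beta, annotation,
        samples.lines_of_class(PARTHENOTE_ESC), samples.lines_of_class(CONVENTIONAL_ESC),
        delta=delta, aggregation=aggregation,
    )

    return {
        "t1": {"value": n, "n": n},
        "t2": {"value": sites0.n_genes, "n": n},
        "t3": {"value": sites1.n_genes, "n": sites1.n_sites},
        "t4": {"value": report.n_definitive_sites + report.n_unknown_direction, "n": n},
        "t5": {"value": 100.0 * report.consistency_fraction, "n": report.n_definitive_sites},
        "t6": {"value": diff.n_differential, "n": len(diff.frame)},
    }
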
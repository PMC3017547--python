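"""Three-state methylation calling and the tissue partial-methylation filter.

Imprinted loci are expected partially methylated in biparental tissue, so
the filter keeps imprinted-gene probes called ``partial`` in at least
(N_tissue - d) tissue lines, where the discordance parameter d relaxes the
unanimity requirement one tissue sample at a time.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedResultError, ValidationError
from .types import (
    DEFINITIVE_STATES,
    STATE_FAILED,
    STATE_METHYLATED,
    STATE_PARTIAL,
    STATE_UNMETHYLATED,
    TISSUE,
    BetaMatrix,
    ImprintedSiteSet,
    ProbeAnnotation,
    SampleSheet,
    StateMatrix,
)

DEFAULT_T_LOW = 0.3
DEFAULT_T_HIGH = 0.7


def aggregate_replicates(beta: BetaMatrix, samples: SampleSheet) -> pd.DataFrame:
    """Mean the technical replicates of each line into a probe x line grid.

    A cell is missing only when every replicate is missing.
    """
    missing = [s for s in samples.sample_ids if s not in beta.sample_ids]
    if missing:
        raise ValidationError(f"samples absent from beta matrix: {missing}")
    columns = {}
    for line in samples.line_ids:
        reps = samples.samples_of_line(line)
        if not reps:
            raise ValidationError(f"line {line!r} has no samples")
        columns[line] = beta.values[reps].mean(axis=1)
    return pd.DataFrame(columns, index=beta.probe_ids)


def call_states(
    line_beta: pd.DataFrame,
    t_low: float = DEFAULT_T_LOW,
    t_high: float = DEFAULT_T_HIGH,
) -> StateMatrix:
    """Call unmethylated (beta <= t_low), methylated (beta >= t_high), else partial.

    Boundary values go to the definitive states; missing values become
    ``failed``.
    """
    if not (0.0 < t_low < t_high < 1.0):
        raise ValidationError(
            f"thresholds must satisfy 0 < t_low < t_high < 1, got ({t_low}, {t_high})"
        )
    arr = line_beta.to_numpy(dtype=float)
    states = np.full(arr.shape, STATE_PARTIAL, dtype=object)
    with np.errstate(invalid="ignore"):
        states[arr <= t_low] = STATE_UNMETHYLATED
        states[arr >= t_high] = STATE_METHYLATED
    states[np.isnan(arr)] = STATE_FAILED
    return StateMatrix(
        states=pd.DataFrame(states, index=line_beta.index, columns=line_beta.columns),
        t_low=t_low,
        t_high=t_high,
    )


def _tissue_lines(states: StateMatrix, samples: SampleSheet) -> list[str]:
    lines = [ln for ln in samples.lines_of_class(TISSUE) if ln in states.line_ids]
    if not lines:
        raise ValidationError("no tissue lines available for the partial-methylation filter")
    return lines


def tissue_partial_filter(
    states: StateMatrix,
    annotation: ProbeAnnotation,
    samples: SampleSheet,
    d: int = 0,
) -> ImprintedSiteSet:
    """Keep imprinted-gene probes partial in >= (N_tissue - d) tissue lines.

    Failed tissue calls count against retention.
    """
    tissue = _tissue_lines(states, samples)
    n_tissue = len(tissue)
    if not (0 <= d <= n_tissue):
        raise ValidationError(f"discordance d={d} outside [0, {n_tissue}]")

    imprinted = annotation.imprinted_probe_ids
    imprinted = imprinted[imprinted.isin(states.probe_ids)]
    tissue_states = states.states.loc[imprinted, tissue]
    n_partial = (tissue_states == STATE_PARTIAL).sum(axis=1)
    n_nonfailed = (tissue_states != STATE_FAILED).sum(axis=1)
    # at d = n_tissue the partial requirement is vacuous, but probes whose
    # tissue calls all failed still carry no evidence and are never retained
    retained = imprinted[(n_partial >= (n_tissue - d)) & (n_nonfailed >= 1)]

    genes = sorted(annotation.frame.loc[retained, "gene_symbol"].unique())
    return ImprintedSiteSet(
        discordance=d,
        probe_ids=list(retained),
        states=states.states.loc[retained].copy(),
        genes=genes,
    )


def discordance_sweep(
    states: StateMatrix,
    annotation: ProbeAnnotation,
    samples: SampleSheet,
    d_max: int,
) -> pd.DataFrame:
    """One (d, n_sites, n_genes) row per discordance level 0..d_max."""
    n_tissue = len(_tissue_lines(states, samples))
    if d_max > n_tissue:
        raise ValidationError(f"d_max={d_max} exceeds the {n_tissue} tissue lines")
    rows = []
    for d in range(d_max + 1):
        site_set = tissue_partial_filter(states, annotation, samples, d)
        rows.append({"d": d, "n_sites": site_set.n_sites, "n_genes": site_set.n_genes})
    return pd.DataFrame(rows)


def definitive_fraction(
    states: StateMatrix,
    sites: ImprintedSiteSet,
    lines: Sequence[str],
) -> float:
    """(#unmethylated + #methylated) / (#unmethylated + #methylated + #partial)
    over all (retained site, group line) calls; failed calls are excluded.
    """
    lines = list(lines)
    if not lines:
        raise ValidationError("group has no lines")
    if sites.n_sites == 0:
        raise ValidationError("site set is empty")
    missing = [ln for ln in lines if ln not in states.line_ids]
    if missing:
        raise ValidationError(f"lines absent from state matrix: {missing}")
    calls = states.states.loc[sites.probe_ids, lines].to_numpy(dtype=object).ravel()
    n_def = int(np.isin(calls, DEFINITIVE_STATES).sum())
    n_partial = int((calls == STATE_PARTIAL).sum())
    if n_def + n_partial == 0:
        raise UndefinedResultError("no non-failed calls; definitive fraction undefined")
    return n_def / (n_def + n_partial)


def baseline_normalize_fraction(group_fraction: float, tissue_fraction: float) -> float:
    """Subtract the tissue-group definitive fraction as the baseline."""
    for name, v in (("group_fraction", group_fraction), ("tissue_fraction", tissue_fraction)):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{name} must be in [0, 1]")
    return group_fraction - tissue_fraction
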
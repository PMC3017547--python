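"""Group-level analyses: uniparental-origin consistency, differential
methylation of imprinted genes, correlation clustering, and the
agreement-vs-correlation curves.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .types import (
    DEFINITIVE_STATES,
    DIRECTION_UNKNOWN,
    MATERNALLY_METHYLATED,
    PATERNALLY_METHYLATED,
    STATE_FAILED,
    STATE_METHYLATED,
    STATE_PARTIAL,
    STATE_UNMETHYLATED,
    BetaMatrix,
    ConsistencyReport,
    Dendrogram,
    DifferentialTable,
    ImprintedSiteSet,
    ProbeAnnotation,
    SampleSheet,
    StateMatrix,
)


def group_state(states: StateMatrix, probe_id: str, lines: Sequence[str]) -> str:
    """Aggregate a group's calls at one probe.

    Unanimity rule: if every non-failed line call agrees the shared state is
    returned; disagreement degrades to ``partial`` (a mixed group is not
    definitively uniparental); all-failed stays ``failed``.
    """
    calls = [states.states.at[probe_id, ln] for ln in lines]
    calls = [c for c in calls if c != STATE_FAILED]
    if not calls:
        return STATE_FAILED
    if all(c == calls[0] for c in calls):
        return str(calls[0])
    return STATE_PARTIAL


def maternal_consistency(
    sites: ImprintedSiteSet,
    states: StateMatrix,
    annotation: ProbeAnnotation,
    parthenote_lines: Sequence[str],
) -> ConsistencyReport:
    """Score definitive parthenote calls against a maternal-only genome.

    A definitive site is consistent when a maternally methylated DMR is
    called methylated, or a paternally methylated DMR is called
    unmethylated. Sites with unknown direction are excluded and counted
    separately.
    """
    parthenote_lines = list(parthenote_lines)
    if not parthenote_lines:
        raise ValidationError("parthenote group is empty")
    if sites.n_sites == 0:
        raise ValidationError("site set is empty")

    rows = []
    for probe in sites.probe_ids:
        direction = annotation.direction_of(probe)
        observed = group_state(states, probe, parthenote_lines)
        definitive = observed in DEFINITIVE_STATES
        if definitive and direction != DIRECTION_UNKNOWN:
            consistent = (
                direction == MATERNALLY_METHYLATED and observed == STATE_METHYLATED
            ) or (direction == PATERNALLY_METHYLATED and observed == STATE_UNMETHYLATED)
        else:
            consistent = False
        rows.append(
            {
                "probe_id": probe,
                "imprint_direction": direction,
                "observed_state": observed,
                "definitive": definitive,
                "consistent": consistent,
            }
        )
    detail = pd.DataFrame(rows).set_index("probe_id")

    definitive = detail[detail["definitive"]]
    known = definitive[definitive["imprint_direction"] != DIRECTION_UNKNOWN]
    n_unknown = int(len(definitive) - len(known))
    if len(definitive) > 0 and len(known) == 0:
        raise ValidationError(
            "all definitive sites have unknown parental direction; "
            "supply imprint_direction in the probe annotation"
        )
    return ConsistencyReport(
        n_definitive_sites=int(len(known)),
        n_consistent=int(known["consistent"].sum()),
        n_unknown_direction=n_unknown,
        detail=detail,
    )


def differential_imprinted(
    line_beta: pd.DataFrame,
    annotation: ProbeAnnotation,
    group_a: Sequence[str],
    group_b: Sequence[str],
    delta: float = 0.2,
    aggregation: str = "gene_mean",
) -> DifferentialTable:
    """Flag imprinted genes whose group-mean beta differs by at least ``delta``.

    ``gene_mean`` compares the flat mean over (gene probes x group lines);
    ``any_probe`` flags a gene if any single probe's group-mean difference
    reaches ``delta`` (the reported difference is then the largest-magnitude
    probe difference).
    """
    if not (0.0 < delta < 1.0):
        raise ValidationError("delta must be in (0, 1)")
    if aggregation not in ("gene_mean", "any_probe"):
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValidationError("both groups must be non-empty")

    imp = annotation.frame[annotation.frame["is_imprinted_gene"].astype(bool)]
    rows = []
    n_excluded = 0
    for gene, probes in imp.groupby("gene_symbol").groups.items():
        probes = [p for p in probes if p in line_beta.index]
        if not probes:
            n_excluded += 1
            continue
        a = line_beta.loc[probes, group_a]
        b = line_beta.loc[probes, group_b]
        if aggregation == "gene_mean":
            diff = float(np.nanmean(a.to_numpy()) - np.nanmean(b.to_numpy()))
        else:
            probe_diff = a.mean(axis=1) - b.mean(axis=1)
            if probe_diff.isna().all():
                n_excluded += 1
                continue
            diff = float(probe_diff.loc[probe_diff.abs().idxmax()])
        if np.isnan(diff):
            n_excluded += 1
            continue
        rows.append({"gene": gene, "difference": diff, "is_differential": abs(diff) >= delta})
    if n_excluded:
        warnings.warn(f"{n_excluded} imprinted gene(s) excluded for lack of data")
    frame = pd.DataFrame(rows, columns=["gene", "difference", "is_differential"]).set_index("gene")
    return DifferentialTable(
        frame=frame, delta=delta, aggregation=aggregation, n_excluded_genes=n_excluded
    )


def sample_correlation_matrix(
    beta: BetaMatrix | pd.DataFrame,
    probes: Iterable[str] | None = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Pairwise sample correlation over probes non-missing in both samples.

    ``method`` is ``pearson`` (default) or ``spearman``. Pairs sharing fewer
    than two probes become missing cells with a warning.
    """
    values = beta.values if isinstance(beta, BetaMatrix) else beta
    if probes is not None:
        values = values.loc[[p for p in probes if p in values.index]]
    if values.shape[1] < 2:
        raise ValidationError("need at least two samples for a correlation matrix")
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    corr = values.corr(method=method, min_periods=2)
    np.fill_diagonal(corr.to_numpy(), 1.0)
    n_missing = int(corr.isna().sum().sum())
    if n_missing:
        warnings.warn(f"{n_missing} sample pair(s) share fewer than 2 probes; cells left missing")
    return corr


def hierarchical_cluster(correlations: pd.DataFrame) -> Dendrogram:
    """Average-linkage agglomeration under distance 1 - correlation.

    Sample labels are sorted lexicographically before linkage so that ties
    break deterministically regardless of input column order.
    """
    if correlations.isna().any().any():
        raise ValidationError("correlation matrix contains missing cells")
    if not correlations.index.equals(correlations.columns):
        raise ValidationError("correlation matrix must be square with matching labels")
    labels = sorted(map(str, correlations.columns))
    ordered = correlations.loc[labels, labels].to_numpy(dtype=float)
    dist = 1.0 - ordered
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrize fp jitter
    condensed = squareform(dist, checks=False)
    z = scipy_linkage(condensed, method="average")
    return Dendrogram(linkage=z, labels=labels)


def discordance_correlation_curve(
    line_beta: pd.DataFrame,
    states: StateMatrix,
    annotation: ProbeAnnotation,
    samples: SampleSheet,
    reference_lines: Sequence[str],
    k_max: int,
    site_mode: str = "all_sites",
) -> pd.DataFrame:
    """Correlation of every line with the reference-group mean profile, as the
    within-reference agreement requirement is relaxed.

    For each k in 0..k_max, sites are kept where at least (n_ref - k)
    reference lines share the same non-failed state call; each line's beta
    profile is then correlated with the reference-group mean over those
    sites. ``site_mode`` restricts the universe to ``all_sites`` or
    ``imprinted_sites``.
    """
    reference_lines = list(reference_lines)
    n_ref = len(reference_lines)
    if n_ref < 2:
        raise ValidationError("reference group needs at least two lines")
    if not (0 <= k_max <= n_ref):
        raise ValidationError(f"k_max={k_max} outside [0, {n_ref}]")
    if site_mode not in ("all_sites", "imprinted_sites"):
        raise ValidationError(f"unknown site_mode {site_mode!r}")

    if site_mode == "imprinted_sites":
        universe = annotation.imprinted_probe_ids
        universe = universe[universe.isin(line_beta.index)]
    else:
        universe = line_beta.index

    ref_states = states.states.loc[universe, reference_lines]
    # per probe: the largest number of reference lines sharing one non-failed state
    agreement = pd.Series(0, index=universe, dtype=int)
    for state in (STATE_UNMETHYLATED, STATE_PARTIAL, STATE_METHYLATED):
        agreement = np.maximum(agreement, (ref_states == state).sum(axis=1))

    rows = []
    for k in range(k_max + 1):
        selected = universe[agreement >= max(n_ref - k, 1)]
        if len(selected) == 0:
            warnings.warn(f"no sites selected at k={k}; row skipped")
            continue
        ref_mean = line_beta.loc[selected, reference_lines].mean(axis=1)
        for line in line_beta.columns:
            profile = line_beta.loc[selected, line]
            both = profile.notna() & ref_mean.notna()
            x, y = profile[both].to_numpy(), ref_mean[both].to_numpy()
            if both.sum() < 2 or x.std() == 0 or y.std() == 0:
                r = np.nan  # correlation undefined for constant profiles
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            rows.append(
                {"line_id": line, "k": k, "correlation": r, "n_sites": int(len(selected))}
            )
    return pd.DataFrame(rows, columns=["line_id", "k", "correlation", "n_sites"])
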
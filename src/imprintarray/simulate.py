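"""Synthetic beadarray experiments with planted imprinted DMRs.

Generates paired methylated/unmethylated signal grids, a sample sheet with
uniparental (parthenote) and biparental ES lines, primary lines, tissue
samples and triplicate normalization controls, plus the ground truth needed
to score every downstream stage.

Generative model, per probe p and sample s with true mean m[p, s]:

    beta* ~ Beta(m * kappa, (1 - m) * kappa)     (beta* = m when kappa is inf)
    T     ~ LogNormal(total_intensity_log_mean, total_intensity_log_sd)
    methylated = beta* * T,  unmethylated = (1 - beta*) * T

True means encode the uniparental expectation: at a planted DMR the
biparental classes sit at 0.5 while the parthenote class sits at 1
(maternally methylated) or 0 (paternally methylated). Controls are fixed at
1 / 0 / 0.5 everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import (
    CONTROL_FULL_METHYL,
    CONTROL_HALF_METHYL,
    CONTROL_UNMETHYL,
    CONVENTIONAL_ESC,
    DIRECTION_UNKNOWN,
    MATERNALLY_METHYLATED,
    PARTHENOTE_ESC,
    PATERNALLY_METHYLATED,
    PRIMARY_CELL,
    SAMPLE_CLASSES,
    TISSUE,
    GroundTruth,
    ProbeAnnotation,
    SampleSheet,
    SignalMatrix,
)

_ENDPOINT_EPS = 64 * np.finfo(float).eps  # jitter for degenerate beta endpoints


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic experiment.

    ``kappa`` is the beta-distribution concentration of probe-level noise;
    ``math.inf`` yields noise-free fractions equal to the true means.
    ``esc_shift`` adds a shared hypermethylation offset to both ES-cell
    classes at a random ``esc_shift_fraction`` of non-imprinted probes so
    that ES lines cluster apart from tissue/primary samples, as in the
    study design this emulates; set the fraction to 0 for a generator in
    which non-DMR probes share one mean across every class.
    """

    n_probes: int = 5000
    n_imprinted_genes: int = 47
    probes_per_imprinted_gene: int = 4
    dmr_fraction_within_imprinted_genes: float = 0.5
    maternal_direction_fraction: float = 0.6
    n_tissue: int = 5
    n_hesc_lines: int = 2
    n_phesc_lines: int = 5
    n_primary_lines: int = 4
    replicates_per_line: int = 2
    control_triplicates: int = 3
    kappa: float = 50.0
    total_intensity_log_mean: float = 9.0
    total_intensity_log_sd: float = 0.4
    background_low_mean: float = 0.1
    background_high_mean: float = 0.9
    background_low_weight: float = 0.7
    esc_shift: float = 0.3
    esc_shift_fraction: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_probes <= 0:
            raise ValidationError("n_probes must be positive")
        if self.n_imprinted_genes <= 0 or self.probes_per_imprinted_gene <= 0:
            raise ValidationError("imprinted gene/probe counts must be positive")
        if self.n_imprinted_genes * self.probes_per_imprinted_gene > self.n_probes:
            raise ValidationError(
                "n_imprinted_genes * probes_per_imprinted_gene exceeds n_probes"
            )
        if not (0.0 <= self.dmr_fraction_within_imprinted_genes <= 1.0):
            raise ValidationError("dmr_fraction_within_imprinted_genes must be in [0, 1]")
        for name in ("maternal_direction_fraction", "background_low_weight", "esc_shift_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1]")
        if not self.kappa > 0:
            raise ValidationError("kappa must be positive")
        for name in (
            "n_tissue",
            "n_hesc_lines",
            "n_phesc_lines",
            "n_primary_lines",
            "replicates_per_line",
            "control_triplicates",
        ):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("background_low_mean", "background_high_mean", "esc_shift"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1]")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown simulation config keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        if isinstance(kwargs.get("kappa"), str):
            kwargs["kappa"] = float(kwargs["kappa"])  # accepts "inf"
        return cls(**kwargs)


@dataclass(frozen=True)
class SimulatedDataset:
    signals: SignalMatrix
    samples: SampleSheet
    annotation: ProbeAnnotation
    truth: GroundTruth
    config: SimulationConfig


def _build_annotation_and_truth(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[ProbeAnnotation, GroundTruth]:
    n = config.n_probes
    probe_ids = [f"cg{i:07d}" for i in range(n)]

    n_imp_probes = config.n_imprinted_genes * config.probes_per_imprinted_gene
    imp_positions = np.sort(rng.choice(n, size=n_imp_probes, replace=False))
    is_imprinted = np.zeros(n, dtype=bool)
    is_imprinted[imp_positions] = True

    gene_symbol = np.empty(n, dtype=object)
    imp_genes = [f"IMPG{g + 1:03d}" for g in range(config.n_imprinted_genes)]
    for k, pos in enumerate(imp_positions):
        gene_symbol[pos] = imp_genes[k // config.probes_per_imprinted_gene]
    # background genes carry ~2 probes each, echoing the array's probe:gene ratio
    bg_positions = np.flatnonzero(~is_imprinted)
    for k, pos in enumerate(bg_positions):
        gene_symbol[pos] = f"GENE{k // 2 + 1:05d}"

    # per-gene parental direction; DMR status drawn per probe
    gene_maternal = rng.random(config.n_imprinted_genes) < config.maternal_direction_fraction
    is_dmr = np.zeros(n, dtype=bool)
    is_dmr[imp_positions] = rng.random(n_imp_probes) < config.dmr_fraction_within_imprinted_genes
    direction = np.full(n, DIRECTION_UNKNOWN, dtype=object)
    for k, pos in enumerate(imp_positions):
        if is_dmr[pos]:
            g = k // config.probes_per_imprinted_gene
            direction[pos] = MATERNALLY_METHYLATED if gene_maternal[g] else PATERNALLY_METHYLATED

    # background means: bimodal mixture shared across classes
    low = rng.random(n) < config.background_low_weight
    base = np.where(low, config.background_low_mean, config.background_high_mean)

    means = pd.DataFrame(
        {cls: base.copy() for cls in SAMPLE_CLASSES}, index=pd.Index(probe_ids, name="probe_id")
    )

    # shared ES-cell hypermethylation at a slice of non-imprinted probes
    if config.esc_shift_fraction > 0 and config.esc_shift > 0:
        n_shift = int(round(config.esc_shift_fraction * len(bg_positions)))
        shift_pos = rng.choice(bg_positions, size=n_shift, replace=False)
        for cls in (CONVENTIONAL_ESC, PARTHENOTE_ESC):
            col = means[cls].to_numpy()
            col[shift_pos] = np.clip(col[shift_pos] + config.esc_shift, 0.0, 1.0)
            means[cls] = col

    # planted DMRs: biparental classes partial, parthenote uniparental
    dmr_pos = np.flatnonzero(is_dmr)
    for cls in (TISSUE, PRIMARY_CELL, CONVENTIONAL_ESC):
        col = means[cls].to_numpy()
        col[dmr_pos] = 0.5
        means[cls] = col
    col = means[PARTHENOTE_ESC].to_numpy()
    col[dmr_pos] = np.where(direction[dmr_pos] == MATERNALLY_METHYLATED, 1.0, 0.0)
    means[PARTHENOTE_ESC] = col

    means[CONTROL_FULL_METHYL] = 1.0
    means[CONTROL_UNMETHYL] = 0.0
    means[CONTROL_HALF_METHYL] = 0.5

    annotation = ProbeAnnotation(
        pd.DataFrame(
            {
                "gene_symbol": gene_symbol,
                "is_imprinted_gene": is_imprinted,
                "imprint_direction": direction,
            },
            index=pd.Index(probe_ids, name="probe_id"),
        )
    )
    truth = GroundTruth(
        frame=pd.DataFrame(
            {"is_true_dmr": is_dmr, "imprint_direction": direction},
            index=pd.Index(probe_ids, name="probe_id"),
        ),
        class_means=means,
    )
    return annotation, truth


def _build_sample_sheet(config: SimulationConfig) -> SampleSheet:
    rows: list[tuple[str, str, str, int]] = []  # sample_id, line_id, class, replicate

    def add(line: str, cls: str, n_reps: int) -> None:
        for r in range(1, n_reps + 1):
            rows.append((f"{line}_r{r}", line, cls, r))

    for i in range(1, config.n_tissue + 1):
        add(f"tissue_{i}", TISSUE, 1)
    for i in range(1, config.n_primary_lines + 1):
        add(f"primary_{i}", PRIMARY_CELL, 1)
    for i in range(1, config.n_hesc_lines + 1):
        add(f"hESC_{i}", CONVENTIONAL_ESC, config.replicates_per_line)
    for i in range(1, config.n_phesc_lines + 1):
        add(f"phESC_{i}", PARTHENOTE_ESC, config.replicates_per_line)
    add("ctrl_full", CONTROL_FULL_METHYL, config.control_triplicates)
    add("ctrl_unmeth", CONTROL_UNMETHYL, config.control_triplicates)
    add("ctrl_half", CONTROL_HALF_METHYL, config.control_triplicates)

    frame = pd.DataFrame(
        rows, columns=["sample_id", "line_id", "sample_class", "replicate_index"]
    ).set_index("sample_id")
    return SampleSheet(frame)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate one full synthetic experiment; identical seeds give identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    annotation, truth = _build_annotation_and_truth(config, rng)
    samples = _build_sample_sheet(config)

    class_of = samples.frame["sample_class"]
    mean_grid = truth.class_means.loc[:, class_of.to_numpy()].to_numpy(dtype=float)

    if math.isinf(config.kappa):
        beta_star = mean_grid.copy()
    else:
        m = np.clip(mean_grid, _ENDPOINT_EPS, 1.0 - _ENDPOINT_EPS)
        beta_star = rng.beta(m * config.kappa, (1.0 - m) * config.kappa)

    total = rng.lognormal(
        config.total_intensity_log_mean, config.total_intensity_log_sd, size=mean_grid.shape
    )
    index = truth.probe_ids
    columns = samples.sample_ids
    signals = SignalMatrix(
        methylated=pd.DataFrame(beta_star * total, index=index, columns=columns),
        unmethylated=pd.DataFrame((1.0 - beta_star) * total, index=index, columns=columns),
    )
    return SimulatedDataset(signals, samples, annotation, truth, config)


def truth_site_set(truth: GroundTruth, annotation: ProbeAnnotation) -> set[str]:
    """The planted DMR probe set — the oracle the pipeline's site set is scored against."""
    if not truth.probe_ids.equals(annotation.probe_ids):
        raise ValidationError("truth and annotation cover different probe universes")
    return truth.dmr_probe_ids
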
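"""Shared domain types for the methylation-array pipeline.

All tabular payloads are pandas objects; the dataclass wrappers exist to
carry validated invariants and bookkeeping (normalization anchors, calling
thresholds) alongside the grids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError

# ---------------------------------------------------------------------------
# enums (kept as plain strings on disk and in frames)

MATERNALLY_METHYLATED = "maternally_methylated"
PATERNALLY_METHYLATED = "paternally_methylated"
DIRECTION_UNKNOWN = "unknown"
IMPRINT_DIRECTIONS = (MATERNALLY_METHYLATED, PATERNALLY_METHYLATED, DIRECTION_UNKNOWN)

CONVENTIONAL_ESC = "conventional_esc"
PARTHENOTE_ESC = "parthenote_esc"
PRIMARY_CELL = "primary_cell"
TISSUE = "tissue"
CONTROL_FULL_METHYL = "control_full_methyl"
CONTROL_UNMETHYL = "control_unmethyl"
CONTROL_HALF_METHYL = "control_half_methyl"

BIOLOGICAL_CLASSES = (CONVENTIONAL_ESC, PARTHENOTE_ESC, PRIMARY_CELL, TISSUE)
CONTROL_CLASSES = (CONTROL_FULL_METHYL, CONTROL_UNMETHYL, CONTROL_HALF_METHYL)
SAMPLE_CLASSES = BIOLOGICAL_CLASSES + CONTROL_CLASSES

STATE_UNMETHYLATED = "unmethylated"
STATE_PARTIAL = "partial"
STATE_METHYLATED = "methylated"
STATE_FAILED = "failed"
STATES = (STATE_UNMETHYLATED, STATE_PARTIAL, STATE_METHYLATED, STATE_FAILED)
DEFINITIVE_STATES = (STATE_UNMETHYLATED, STATE_METHYLATED)


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbeAnnotation:
    """Per-probe gene assignment and imprinted-gene metadata.

    ``frame`` is indexed by probe_id with columns ``gene_symbol``,
    ``is_imprinted_gene`` (bool) and ``imprint_direction``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_symbol", "is_imprinted_gene", "imprint_direction"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"annotation missing columns: {sorted(missing)}")
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe_id in annotation: {dupes[:5]}")
        bad = set(self.frame["imprint_direction"]) - set(IMPRINT_DIRECTIONS)
        if bad:
            raise ValidationError(f"unknown imprint_direction tokens: {sorted(bad)}")
        directed = self.frame["imprint_direction"] != DIRECTION_UNKNOWN
        if (directed & ~self.frame["is_imprinted_gene"].astype(bool)).any():
            raise ValidationError(
                "imprint_direction set on probes not flagged as imprinted-gene probes"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def imprinted_probe_ids(self) -> pd.Index:
        return self.frame.index[self.frame["is_imprinted_gene"].astype(bool)]

    @property
    def imprinted_genes(self) -> list[str]:
        mask = self.frame["is_imprinted_gene"].astype(bool)
        return sorted(self.frame.loc[mask, "gene_symbol"].unique())

    @property
    def n_imprinted_genes(self) -> int:
        return len(self.imprinted_genes)

    def direction_of(self, probe_id: str) -> str:
        return str(self.frame.at[probe_id, "imprint_direction"])


@dataclass(frozen=True)
class SampleSheet:
    """Sample-to-line/class assignment.

    ``frame`` is indexed by sample_id with columns ``line_id``,
    ``sample_class`` and ``replicate_index``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"line_id", "sample_class", "replicate_index"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        if self.frame.index.has_duplicates:
            raise ValidationError("duplicate sample_id in sample sheet")
        bad = set(self.frame["sample_class"]) - set(SAMPLE_CLASSES)
        if bad:
            raise ValidationError(f"unknown sample_class tokens: {sorted(bad)}")
        if (self.frame["replicate_index"].astype(int) < 1).any():
            raise ValidationError("replicate_index must be a positive integer")
        pairs = self.frame[["line_id", "replicate_index"]]
        if pairs.duplicated().any():
            raise ValidationError("(line_id, replicate_index) pairs must be unique")

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.index

    def samples_of_class(self, sample_class: str) -> list[str]:
        mask = self.frame["sample_class"] == sample_class
        return list(self.frame.index[mask])

    def lines_of_class(self, sample_class: str) -> list[str]:
        mask = self.frame["sample_class"] == sample_class
        # preserve sheet order, deduplicated
        return list(dict.fromkeys(self.frame.loc[mask, "line_id"]))

    def samples_of_line(self, line_id: str) -> list[str]:
        return list(self.frame.index[self.frame["line_id"] == line_id])

    @property
    def line_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["line_id"]))

    @property
    def line_class(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for sid, row in self.frame.iterrows():
            out.setdefault(str(row["line_id"]), str(row["sample_class"]))
        return out


@dataclass(frozen=True)
class SignalMatrix:
    """Paired methylated/unmethylated fluorescence intensities."""

    methylated: pd.DataFrame
    unmethylated: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.methylated.index.equals(self.unmethylated.index) or not (
            self.methylated.columns.equals(self.unmethylated.columns)
        ):
            raise ValidationError("methylated/unmethylated grids have mismatched labels")
        for name, grid in (("methylated", self.methylated), ("unmethylated", self.unmethylated)):
            if (grid.to_numpy(dtype=float) < 0).any():
                raise ValidationError(f"negative values in {name} signal grid")

    @property
    def probe_ids(self) -> pd.Index:
        return self.methylated.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.methylated.columns


@dataclass(frozen=True)
class BetaMatrix:
    """Probe x sample methylation fractions, raw or control-normalized."""

    values: pd.DataFrame
    normalized: bool = False
    anchors: pd.DataFrame | None = None  # recorded per-probe normalization anchors

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            out_of_range = np.nansum((arr < 0) | (arr > 1))
        if out_of_range:
            raise ValidationError("beta values must lie in [0, 1] or be missing")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass(frozen=True)
class ControlProfile:
    """Per-probe control anchors used by range-scaling normalization.

    ``frame`` columns: ``beta_full``, ``beta_zero``, ``beta_half``, ``usable``.
    """

    frame: pd.DataFrame
    eps_range: float

    @property
    def probe_ids(self) -> pd.Index:
        return self.frame.index


@dataclass(frozen=True)
class StateMatrix:
    """Per (probe, line) three-state call plus failure flag."""

    states: pd.DataFrame  # values in STATES
    t_low: float
    t_high: float
    aggregation: str = "replicate_mean"

    def __post_init__(self) -> None:
        if not (0.0 < self.t_low < self.t_high < 1.0):
            raise ValidationError(
                f"thresholds must satisfy 0 < t_low < t_high < 1, got ({self.t_low}, {self.t_high})"
            )
        bad = set(np.unique(self.states.to_numpy(dtype=object))) - set(STATES)
        if bad:
            raise ValidationError(f"unknown state tokens: {sorted(map(str, bad))}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.states.index

    @property
    def line_ids(self) -> pd.Index:
        return self.states.columns


@dataclass(frozen=True)
class ImprintedSiteSet:
    """Probes surviving the tissue partial-methylation filter."""

    discordance: int
    probe_ids: list[str]
    states: pd.DataFrame  # retained probes x all lines
    genes: list[str]

    @property
    def n_sites(self) -> int:
        return len(self.probe_ids)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GroundTruth:
    """Planted simulation truth.

    ``frame``: per probe ``is_true_dmr`` and ``imprint_direction``;
    ``class_means``: probe x sample-class grid of true mean methylation.
    """

    frame: pd.DataFrame
    class_means: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.frame.index.equals(self.class_means.index):
            raise ValidationError("truth frame and class means have mismatched probes")

    @property
    def probe_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def dmr_probe_ids(self) -> set[str]:
        return set(self.frame.index[self.frame["is_true_dmr"].astype(bool)])


@dataclass(frozen=True)
class ConsistencyReport:
    """Uniparental-origin consistency of definitive calls at imprinted sites."""

    n_definitive_sites: int
    n_consistent: int
    n_unknown_direction: int
    detail: pd.DataFrame  # probe, direction, observed_state, definitive, consistent

    @property
    def consistency_fraction(self) -> float:
        if self.n_definitive_sites == 0:
            raise ValidationError("no definitive sites; consistency fraction undefined")
        return self.n_consistent / self.n_definitive_sites


@dataclass(frozen=True)
class DifferentialTable:
    """Per-imprinted-gene group difference in mean methylation."""

    frame: pd.DataFrame  # gene-indexed: difference, is_differential
    delta: float
    aggregation: str
    n_excluded_genes: int = 0

    @property
    def n_differential(self) -> int:
        return int(self.frame["is_differential"].sum())


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative tree over samples under 1 - correlation distance."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]

    def cluster_members(self) -> list[frozenset[str]]:
        """Member sets of every internal node, in merge order."""
        n = len(self.labels)
        members: list[frozenset[str]] = [frozenset([lab]) for lab in self.labels]
        for a, b, _, _ in self.linkage:
            members.append(members[int(a)] | members[int(b)])
        return members[n:]

    def has_exclusive_cluster(self, include: Iterable[str], exclude: Iterable[str]) -> bool:
        """True if the smallest cluster covering ``include`` avoids ``exclude``."""
        inc, exc = set(include), set(exclude)
        for node in self.cluster_members():
            if inc <= node:
                return not (node & exc)
        return False

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Newick rendering with branch lengths from merge heights."""
        n = len(self.labels)
        heights = [0.0] * n + [float(h) for h in self.linkage[:, 2]]

        def render(node: int, parent_height: float) -> str:
            length = parent_height - heights[node]
            if node < n:
                return f"{self.labels[node]}:{length:.6g}"
            a, b = int(self.linkage[node - n, 0]), int(self.linkage[node - n, 1])
            inner = ",".join(render(c, heights[node]) for c in (a, b))
            return f"({inner}):{length:.6g}"

        root = n + len(self.linkage) - 1
        return f"({','.join(render(int(c), heights[root]) for c in (int(self.linkage[-1, 0]), int(self.linkage[-1, 1])))});"


@dataclass(frozen=True)
class CtTable:
    """qPCR cycle-threshold observations.

    ``data`` columns: ``gene``, ``group``, ``replicate``, ``ct`` (NaN means
    not-detected). ``housekeeping_genes`` is the reference-gene set.
    """

    data: pd.DataFrame
    housekeeping_genes: frozenset[str]

    def __post_init__(self) -> None:
        required = {"gene", "group", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"Ct table missing columns: {sorted(missing)}")
        ct = self.data["ct"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nansum((ct < 0) | (ct > 40)):
                raise ValidationError("ct values must lie in [0, 40] or be not-detected")
        if not self.housekeeping_genes:
            raise ValidationError("at least one housekeeping gene is required")
        for group, sub in self.data.groupby("group"):
            if not (set(sub["gene"]) & self.housekeeping_genes):
                raise ValidationError(f"group {group!r} has no housekeeping gene rows")

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.data["group"]))


@dataclass(frozen=True)
class FoldRegulationTable:
    """Per-gene fold change / fold regulation between two groups."""

    frame: pd.DataFrame  # gene-indexed: fold_change, fold_regulation, direction
    test_group: str
    reference_group: str
    threshold: float

    @property
    def counts(self) -> dict[str, int]:
        return {
            k: int((self.frame["direction"] == k).sum())
            for k in ("up", "down", "unchanged")
        }
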
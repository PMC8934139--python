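"""Typed containers and readers/writers for expression matrices, dose designs,
gene annotations, and result tables.

The central container is :class:`ExpressionDataset`: a probes × samples matrix of
log-scale, normalized expression values together with the per-sample dose vector
and the base of the log transform. Columns are canonicalized to ascending dose on
construction so that every downstream statistic is invariant to the column order
of the input file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "DatasetSummary",
    "GeneAnnotation",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_dose_map",
    "summarize_dataset",
    "read_gmt",
    "read_probe_map",
]

_LOG_BASES = {"2": 2.0, "10": 10.0, "natural": math.e, "e": math.e}


def resolve_log_base(log_base) -> float:
    """Map a declared log base (2, 10, or 'natural') to its numeric value."""
    if isinstance(log_base, str):
        key = log_base.strip().lower()
        if key not in _LOG_BASES:
            raise ValueError(f"unsupported log base {log_base!r}; use 2, 10 or 'natural'")
        return _LOG_BASES[key]
    base = float(log_base)
    if base <= 1.0:
        raise ValueError(f"log base must exceed 1, got {base}")
    return base


@dataclass
class ExpressionDataset:
    """Probes × samples log-scale expression matrix with a dose design.

    Parameters
    ----------
    probe_ids : sequence of str
        Unique probe identifiers, one per matrix row.
    values : ndarray, shape (n_probes, n_samples)
        Log-scale normalized intensities. Non-finite entries are permitted at
        construction (they mark invalid probes) but invalid probes are excluded
        from all statistics.
    doses : ndarray, shape (n_samples,)
        Non-negative dose administered to each sample. The minimum dose group
        is treated as the control; it need not be literally zero.
    log_base : float or {2, 10, 'natural'}
        Base of the log transform applied upstream of this package.
    sample_ids : sequence of str
        Unique sample identifiers, one per column.
    dose_units : str
        Free-text dose units, carried through to outputs.
    """

    probe_ids: list
    values: np.ndarray
    doses: np.ndarray
    log_base: float = 2.0
    sample_ids: list = None
    dose_units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.doses = np.asarray(self.doses, dtype=float)
        self.probe_ids = list(self.probe_ids)
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(self.values.shape[1])]
        self.sample_ids = list(self.sample_ids)
        self.log_base = resolve_log_base(self.log_base)
        self._validate()
        self._canonicalize()

    def _validate(self) -> None:
        n_probes, n_samples = self.values.shape
        if len(self.probe_ids) != n_probes:
            raise ValueError("probe_ids length does not match matrix rows")
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length does not match matrix columns")
        if len(self.doses) != n_samples:
            raise ValueError("doses length does not match sample count")
        dup = _first_duplicate(self.probe_ids)
        if dup is not None:
            raise ValueError(f"duplicate probe id: {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValueError(f"duplicate sample id: {dup!r}")
        if np.any(~np.isfinite(self.doses)) or np.any(self.doses < 0):
            raise ValueError("doses must be finite and non-negative")
        if len(np.unique(self.doses)) < 2:
            raise ValueError("at least 2 distinct dose levels are required")

    def _canonicalize(self) -> None:
        # stable sort: ties in dose keep the input sample order
        order = np.argsort(self.doses, kind="stable")
        self.doses = self.doses[order]
        self.values = self.values[:, order]
        self.sample_ids = [self.sample_ids[i] for i in order]

    # -- design geometry ---------------------------------------------------

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def dose_levels(self) -> np.ndarray:
        """Distinct doses in ascending order; the first is the control level."""
        return np.unique(self.doses)

    @property
    def control_dose(self) -> float:
        return float(self.dose_levels[0])

    @property
    def max_dose(self) -> float:
        return float(self.dose_levels[-1])

    def group_indices(self) -> list:
        """Column index arrays per dose level, ascending dose."""
        return [np.flatnonzero(self.doses == d) for d in self.dose_levels]

    def group_sizes(self) -> np.ndarray:
        return np.array([idx.size for idx in self.group_indices()])

    def probe_values(self, probe_id: str) -> np.ndarray:
        return self.values[self.probe_index(probe_id)]

    def probe_index(self, probe_id: str) -> int:
        try:
            return self._probe_lookup[probe_id]
        except AttributeError:
            self._probe_lookup = {p: i for i, p in enumerate(self.probe_ids)}
            return self._probe_lookup[probe_id]

    def group_means(self, probe_id: str) -> np.ndarray:
        y = self.probe_values(probe_id)
        return np.array([y[idx].mean() for idx in self.group_indices()])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.probe_ids, name="probe_id"),
                            columns=self.sample_ids)


@dataclass
class DatasetSummary:
    """Validity summary of an :class:`ExpressionDataset`."""

    n_dose_levels: int
    n_samples_per_level: list
    n_valid_probes: int
    n_invalid_probes: int
    invalid_reasons: dict  # probe_id -> reason, only for invalid probes

    @property
    def valid_probe_mask(self):
        return self._mask

    def to_frame(self) -> pd.DataFrame:
        rows = [{"probe_id": p, "reason": r} for p, r in self.invalid_reasons.items()]
        return pd.DataFrame(rows, columns=["probe_id", "reason"])


@dataclass
class GeneAnnotation:
    """Probe→gene mapping plus gene-set categories.

    ``probe_to_genes`` maps each probe id to the *set* of gene ids it measures;
    probes hitting more than one gene are removed during gene-level aggregation.
    ``categories`` maps a category id to ``(name, set_of_gene_ids)``.
    """

    probe_to_genes: dict = field(default_factory=dict)
    categories: dict = field(default_factory=dict)
    source_label: str = "gene-id"

    def __post_init__(self):
        for cid, (name, genes) in self.categories.items():
            if not genes:
                raise ValueError(f"category {cid!r} has no genes")
            for g in genes:
                if not isinstance(g, str) or not g:
                    raise ValueError(f"category {cid!r} contains an empty gene id")

    @property
    def universe(self) -> set:
        """All genes measured by uniquely-mapping probes on the platform."""
        return {next(iter(gs)) for gs in self.probe_to_genes.values() if len(gs) == 1}


def _first_duplicate(items):
    seen = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


def _read_table(path) -> pd.DataFrame:
    """Read a delimited text table, auto-detecting tab vs comma."""
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") else ","
    return pd.read_csv(path, sep=sep, index_col=0, comment="#",
                       float_precision="round_trip")


def read_dose_map(path) -> dict:
    """Read a two-column sample→dose table (header optional for 'sample_id,dose')."""
    df = _read_table(path)
    col = df.columns[0]
    return {str(s): float(d) for s, d in df[col].items()}


def read_expression_matrix(path, dose_map: Mapping[str, float], log_base=2,
                           dose_units: str = "") -> ExpressionDataset:
    """Read a probes × samples delimited matrix into an :class:`ExpressionDataset`.

    The file must have a header row of sample ids and probe ids in the first
    column. Every sample must appear in ``dose_map``. Columns are re-sorted by
    ascending dose (stable for ties).
    """
    df = _read_table(path)
    probe_ids = [str(p) for p in df.index]
    sample_ids = [str(s) for s in df.columns]
    missing = [s for s in sample_ids if s not in dose_map]
    if missing:
        raise ValueError(f"samples missing a dose: {missing}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in expression matrix {path}: {exc}") from None
    doses = np.array([float(dose_map[s]) for s in sample_ids])
    return ExpressionDataset(probe_ids, values, doses, log_base, sample_ids,
                             dose_units=dose_units)


def write_expression_matrix(ds: ExpressionDataset, path, sep: str = "\t") -> None:
    ds.to_frame().to_csv(path, sep=sep)


def summarize_dataset(ds: ExpressionDataset) -> DatasetSummary:
    """Flag invalid probes (non-finite values or zero variance) and count groups.

    A probe is invalid when any of its values is missing/non-finite, or when it
    is constant across all samples — a zero-variance probe has no within-group
    scatter to standardize trend statistics against.
    """
    finite = np.isfinite(ds.values).all(axis=1)
    with np.errstate(invalid="ignore"):
        variable = np.nanstd(ds.values, axis=1) > 0
    reasons = {}
    for i, probe in enumerate(ds.probe_ids):
        if not finite[i]:
            reasons[probe] = "non-finite value"
        elif not variable[i]:
            reasons[probe] = "zero variance"
    mask = finite & variable
    summary = DatasetSummary(
        n_dose_levels=len(ds.dose_levels),
        n_samples_per_level=ds.group_sizes().tolist(),
        n_valid_probes=int(mask.sum()),
        n_invalid_probes=int((~mask).sum()),
        invalid_reasons=reasons,
    )
    summary._mask = mask
    return summary


def read_gmt(path, source_label: str = "gene-set") -> GeneAnnotation:
    """Read gene-set categories from a GMT file (one set per line:
    ``id<TAB>description<TAB>gene1<TAB>gene2...``)."""
    categories = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line has no genes")
            cid, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{ln}: GMT line has no genes")
            categories[cid] = (desc, set(genes))
    return GeneAnnotation(categories=categories, source_label=source_label)


def read_probe_map(path) -> dict:
    """Read a two-column probe→gene TSV (one row per probe–gene pair).

    Probes listed with multiple gene rows map to a multi-gene set.
    """
    probe_to_genes: dict = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{ln}: malformed probe-map row {line!r}")
            probe_to_genes.setdefault(parts[0], set()).add(parts[1])
    return probe_to_genes
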
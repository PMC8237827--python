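"""Accuracy/precision evaluation of fingerprint classification.

Each reference species is scored one-vs-rest: a 2×2 confusion table
(TP/FP/FN/TN) over the blind queries, from which four metrics are computed:

    accuracy    = (TP+TN)/(TP+FP+FN+TN)
    precision   = TP/(TP+FP)
    sensitivity = TP/(TP+FN)
    specificity = TN/(TN+FP)

A rejected (UNCLASSIFIED) query counts as a negative call for every target,
so it contributes FN for its true species and TN elsewhere. Metrics whose
denominator is zero are reported as undefined (NA), never coerced to 0.

Results aggregate into two table shapes: per-primer rows with a mean column
over species, and per-species means over all primers. The end-to-end blind
trial harness chains panel simulation → reference extraction → library →
query classification → these tables, fully reproducible from one seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace as dc_replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import study
from .matching import (
    UNCLASSIFIED,
    ClassificationResult,
    DiscriminationMatrix,
    ReferenceLibrary,
    build_reference_library,
    classify_combined,
    classify_single_primer,
    discrimination_matrix,
)
from .processing import MeltFingerprint, ProcessingConfig, extract_fingerprint
from .synth import (
    LabeledCurveSet,
    PanelSpec,
    generate_query_set,
    generate_reference_curves,
    make_default_panel,
    subseed,
)

__all__ = [
    "ConfusionCounts",
    "MetricsRow",
    "MetricsTable",
    "TrialConfig",
    "TrialResult",
    "round_half_up",
    "one_vs_rest_confusion",
    "compute_metrics",
    "metrics_table",
    "extract_all",
    "library_from_curves",
    "queries_by_individual",
    "run_blind_trial",
]

METRICS = study.METRICS


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, for presentation only."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest 2×2 counts for a single target species."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsRow:
    """The four metrics as fractions in [0, 1]; None marks an undefined
    metric (zero denominator)."""

    accuracy: Optional[float]
    precision: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]

    def get(self, metric: str) -> Optional[float]:
        return getattr(self, metric)

    def as_percent(self) -> dict[str, Optional[float]]:
        return {m: (None if self.get(m) is None else 100.0 * self.get(m))
                for m in METRICS}


def one_vs_rest_confusion(
    results: Sequence[ClassificationResult | str],
    truths: Sequence[str],
    target: str,
) -> ConfusionCounts:
    """Count TP/FP/FN/TN for one target species.

    ``results`` may be ClassificationResult objects or bare labels; an
    UNCLASSIFIED call is a negative for every target.
    """
    if len(results) == 0:
        raise ValueError("no classification results to evaluate")
    if len(results) != len(truths):
        raise ValueError("results and truths are not aligned")
    tp = fp = fn = tn = 0
    for r, truth in zip(results, truths):
        label = r if isinstance(r, str) else r.label
        called = label == target
        is_target = truth == target
        if called and is_target:
            tp += 1
        elif called:
            fp += 1
        elif is_target:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def compute_metrics(c: ConfusionCounts) -> MetricsRow:
    """Accuracy/precision/sensitivity/specificity from a 2×2 table."""
    if c.n == 0:
        raise ValueError("empty confusion table")

    def ratio(num: int, den: int) -> Optional[float]:
        return None if den == 0 else num / den

    return MetricsRow(
        accuracy=(c.tp + c.tn) / c.n,
        precision=ratio(c.tp, c.tp + c.fp),
        sensitivity=ratio(c.tp, c.tp + c.fn),
        specificity=ratio(c.tn, c.tn + c.fp),
    )


@dataclass(frozen=True)
class MetricsTable:
    """Per-primer × per-species metrics with their aggregation means.

    ``per_primer`` is a DataFrame in percent with a (primer, metric) row
    MultiIndex, one column per species and a trailing "Mean" column (mean
    over species). ``per_species`` has one row per species and one column
    per metric: the mean over all primers. Means are computed on unrounded
    values and skip undefined (NaN) cells; any skipped cell is listed in
    ``incomplete_cells``. Rounding happens only at presentation
    (``rounded``, ``to_tsv``).
    """

    per_primer: pd.DataFrame
    per_species: pd.DataFrame
    incomplete_cells: tuple[tuple[str, str, str], ...] = ()

    def rounded(self, ndigits: int = 2) -> "MetricsTable":
        return MetricsTable(
            per_primer=self.per_primer.map(
                lambda v: np.nan if pd.isna(v) else round_half_up(v, ndigits)),
            per_species=self.per_species.map(
                lambda v: np.nan if pd.isna(v) else round_half_up(v, ndigits)),
            incomplete_cells=self.incomplete_cells,
        )

    def to_tsv(self, per_primer_path, per_species_path, na: str = "NA") -> None:
        r = self.rounded()
        r.per_primer.to_csv(per_primer_path, sep="\t", na_rep=na)
        r.per_species.to_csv(per_species_path, sep="\t", na_rep=na)


def metrics_table(
    rows: Mapping[tuple[str, str], MetricsRow],
    primers: Optional[Sequence[str]] = None,
    species: Optional[Sequence[str]] = None,
) -> MetricsTable:
    """Assemble the two aggregation tables from per-(primer, species) rows."""
    if primers is None:
        primers = sorted({p for p, _ in rows})
    if species is None:
        species = sorted({s for _, s in rows})
    incomplete = []
    index = pd.MultiIndex.from_tuples(
        [(p, m) for p in primers for m in METRICS], names=["primer", "metric"]
    )
    table = pd.DataFrame(index=index, columns=list(species), dtype=float)
    for p in primers:
        for s in species:
            row = rows.get((p, s))
            for m in METRICS:
                v = None if row is None else row.get(m)
                if v is None:
                    incomplete.append((p, s, m))
                    table.loc[(p, m), s] = np.nan
                else:
                    table.loc[(p, m), s] = 100.0 * v
    table["Mean"] = table[list(species)].mean(axis=1, skipna=True)
    per_species = pd.DataFrame(index=list(species), columns=list(METRICS),
                               dtype=float)
    for s in species:
        for m in METRICS:
            cells = table.loc[[(p, m) for p in primers], s]
            per_species.loc[s, m] = cells.mean(skipna=True)
    return MetricsTable(per_primer=table, per_species=per_species,
                        incomplete_cells=tuple(incomplete))


def study_tables() -> MetricsTable:
    """The published per-primer × per-species percentages, re-aggregated.

    The per-cell values are fixed inputs (human-judged real curves); only
    the row/column means are recomputed here.
    """
    rows = {}
    for p, metrics in study.PUBLISHED_CELL_PCT.items():
        for i, s in enumerate(study.REFERENCE_SPECIES):
            rows[(p, s)] = MetricsRow(**{m: metrics[m][i] / 100.0 for m in METRICS})
    return metrics_table(rows, primers=list(study.PUBLISHED_CELL_PCT),
                         species=list(study.REFERENCE_SPECIES))


# ---------------------------------------------------------------------------
# End-to-end blind trial
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialConfig:
    """Everything needed to reproduce one simulated double-blind trial."""

    seed: int = 0
    panel: Optional[PanelSpec] = None
    query_counts: Optional[dict[str, int]] = None
    replicates: int = 3
    tm_jitter_sd: Optional[float] = None
    noise_sd: Optional[float] = None
    amplitude_jitter_cv: Optional[float] = None
    processing: ProcessingConfig = ProcessingConfig()
    tolerance: float = 0.3
    unmatched_penalty: float = 1.0
    reject_threshold: float = 0.5
    uniqueness_threshold: float = 0.25
    primers: Optional[tuple[str, ...]] = None
    min_replicate_support: float = 0.5
    combined_sets: tuple[tuple[str, ...], ...] = ()
    with_discrimination: bool = True


@dataclass(frozen=True)
class TrialResult:
    config: TrialConfig
    library: ReferenceLibrary
    results: dict[str, tuple[ClassificationResult, ...]]  # primer → per-query
    truths: tuple[str, ...]
    metrics: MetricsTable
    confusions: dict[tuple[str, str], ConfusionCounts]
    combined_results: dict[tuple[str, ...], tuple[ClassificationResult, ...]]
    discrimination: tuple[DiscriminationMatrix, ...]

    @property
    def n_queries(self) -> int:
        return len(self.truths)

    def accuracy_of(self, primer: str) -> float:
        """Plain fraction of correct assignments for one primer."""
        res = self.results[primer]
        return sum(r.label == t for r, t in zip(res, self.truths)) / len(res)

    def accuracy_of_combined(self, primer_set: tuple[str, ...]) -> float:
        """Fraction of correct assignments for a primer combination."""
        res = self.combined_results[tuple(primer_set)]
        return sum(r.label == t for r, t in zip(res, self.truths)) / len(res)


def extract_all(
    curves: LabeledCurveSet, config: ProcessingConfig = ProcessingConfig()
) -> list[tuple[MeltFingerprint, str, Optional[str], str]]:
    """Fingerprint every labeled curve; returns (fp, species, population, id)."""
    out = []
    for rec in curves:
        fp = extract_fingerprint(rec.curve, config)
        out.append((fp, rec.species, rec.population, rec.replicate_id))
    return out


def library_from_curves(
    curves: LabeledCurveSet,
    config: ProcessingConfig = ProcessingConfig(),
    min_replicate_support: float = 0.5,
    tolerance: float = 0.3,
) -> ReferenceLibrary:
    """Extract fingerprints from labeled replicate curves and build the
    consensus reference library."""
    grouped: dict[tuple[str, str], list[MeltFingerprint]] = {}
    for fp, sp, _pop, _rid in extract_all(curves, config):
        grouped.setdefault((sp, fp.primer), []).append(fp)
    return build_reference_library(grouped, min_replicate_support, tolerance)


def queries_by_individual(
    curves: LabeledCurveSet, config: ProcessingConfig = ProcessingConfig()
) -> dict[str, tuple[str, dict[str, MeltFingerprint]]]:
    """Group query curves per individual: id → (true species, primer → fp)."""
    out: dict[str, tuple[str, dict[str, MeltFingerprint]]] = {}
    for fp, sp, _pop, rid in extract_all(curves, config):
        if rid not in out:
            out[rid] = (sp, {})
        out[rid][1][fp.primer] = fp
    return out


def run_blind_trial(cfg: TrialConfig) -> TrialResult:
    """Simulate and score one full double-blind identification trial.

    Stages: default panel → replicate reference curves → consensus library
    → labeled query set (study counts by default) → fingerprint extraction
    → per-primer nearest-reference classification → one-vs-rest metrics in
    both table shapes → pairwise discrimination matrices. Deterministic in
    ``cfg.seed``.
    """
    panel = cfg.panel if cfg.panel is not None else make_default_panel(cfg.seed)
    updates: dict = {"seed": cfg.seed if cfg.panel is None else panel.seed}
    if cfg.tm_jitter_sd is not None:
        updates["tm_jitter_sd"] = cfg.tm_jitter_sd
    if cfg.noise_sd is not None:
        updates["noise_sd"] = cfg.noise_sd
    if cfg.amplitude_jitter_cv is not None:
        updates["amplitude_jitter_cv"] = cfg.amplitude_jitter_cv
    if cfg.primers is not None:
        updates["primers"] = tuple(cfg.primers)
    panel = dc_replace(panel, **updates)

    ref_curves = generate_reference_curves(panel, cfg.replicates)
    lib = library_from_curves(ref_curves, cfg.processing,
                              cfg.min_replicate_support, cfg.tolerance)

    counts = cfg.query_counts if cfg.query_counts is not None else dict(study.QUERY_COUNTS)
    counts = {sp: n for sp, n in counts.items() if n > 0}
    qcurves = generate_query_set(panel, counts,
                                 seed=subseed(cfg.seed, "trial-queries"))
    individuals = queries_by_individual(qcurves, cfg.processing)
    ids = sorted(individuals)
    truths = tuple(individuals[i][0] for i in ids)

    results: dict[str, tuple[ClassificationResult, ...]] = {}
    for pr in panel.primers:
        res = []
        for i in ids:
            fp = individuals[i][1][pr]
            r = classify_single_primer(fp, lib, pr, cfg.tolerance,
                                       cfg.reject_threshold, cfg.unmatched_penalty)
            res.append(dc_replace(r, query_id=i))
        results[pr] = tuple(res)

    confusions: dict[tuple[str, str], ConfusionCounts] = {}
    rows: dict[tuple[str, str], MetricsRow] = {}
    eval_species = sorted(counts)
    for pr in panel.primers:
        for sp in eval_species:
            c = one_vs_rest_confusion(results[pr], truths, sp)
            confusions[(pr, sp)] = c
            rows[(pr, sp)] = compute_metrics(c)
    table = metrics_table(rows, primers=list(panel.primers), species=eval_species)

    combined_results = {}
    for pset in cfg.combined_sets:
        res = []
        for i in ids:
            r = classify_combined(individuals[i][1], lib, pset, cfg.tolerance,
                                  cfg.reject_threshold, cfg.unmatched_penalty)
            res.append(dc_replace(r, query_id=i))
        combined_results[tuple(pset)] = tuple(res)

    disc: tuple[DiscriminationMatrix, ...] = ()
    if cfg.with_discrimination:
        singles = [(p,) for p in panel.primers]
        pairs = list(itertools.combinations(panel.primers, 2))
        disc = tuple(discrimination_matrix(
            lib, singles + pairs, cfg.uniqueness_threshold, cfg.tolerance,
            cfg.unmatched_penalty))

    return TrialResult(config=cfg, library=lib, results=results, truths=truths,
                       metrics=table, confusions=confusions,
                       combined_results=combined_results, discrimination=disc)
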
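"""Reference libraries, peak-list alignment, and Tm-pattern classification.

A query is identified by comparing its melting fingerprint (ordered Tm peak
list) against archived per-species consensus fingerprints. Comparison is a
monotone one-to-one alignment of the two sorted peak lists: melting peaks
are ordered by temperature, so crossing matches are physically meaningless.
Among all alignments whose matched pairs agree within a Tm tolerance, the
one maximizing the matched-pair count and then minimizing the total |ΔTm|
is chosen (dynamic programming). The alignment is summarized as a bounded
dissimilarity

    d = (Σ_matched |ΔTm|/tol + λ·u) / (n_matched + u),

where u counts unmatched peaks on both sides and λ (default 1) is the
penalty per unmatched peak; d = 0 iff the peak sets match exactly and
d ≤ λ always (for λ ≥ 1).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .processing import MeltFingerprint, MeltPeak

__all__ = [
    "UNCLASSIFIED",
    "PeakMatching",
    "ReferenceLibrary",
    "ClassificationResult",
    "DiscriminationMatrix",
    "align_peak_lists",
    "fingerprint_distance",
    "build_reference_library",
    "classify_single_primer",
    "classify_combined",
    "discrimination_matrix",
]

logger = logging.getLogger(__name__)

#: Sentinel label for queries rejected by the distance threshold or with an
#: invalid (zero-peak) fingerprint.
UNCLASSIFIED = "UNCLASSIFIED"

#: Default Tm tolerance (°C) for calling two peaks "the same": replicate
#: scatter is ~0.1 °C while within-fingerprint peaks sit >= 0.8 °C apart.
DEFAULT_TOLERANCE = 0.3
DEFAULT_UNMATCHED_PENALTY = 1.0
DEFAULT_REJECT_THRESHOLD = 0.5
DEFAULT_UNIQUENESS_THRESHOLD = 0.25


@dataclass(frozen=True)
class PeakMatching:
    """A monotone one-to-one matching between two sorted peak lists."""

    pairs: tuple[tuple[int, int], ...]
    unmatched_a: tuple[int, ...]
    unmatched_b: tuple[int, ...]
    total_abs_delta: float

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    @property
    def n_unmatched(self) -> int:
        return len(self.unmatched_a) + len(self.unmatched_b)


def align_peak_lists(
    a: MeltFingerprint, b: MeltFingerprint, tolerance: float = DEFAULT_TOLERANCE
) -> PeakMatching:
    """Optimal monotone alignment of two fingerprints.

    Maximizes the number of matched pairs with |ΔTm| ≤ tolerance, breaking
    ties by minimal Σ|ΔTm|. O(n·m) dynamic programming over the two sorted
    Tm lists; equivalent to exhaustive enumeration over all monotone
    matchings.
    """
    ta, tb = a.tms, b.tms
    n, m = len(ta), len(tb)
    NEG = (-1, 0.0)
    # dp[i][j]: best (matches, -cost) using first i of a and j of b
    dp = [[NEG] * (m + 1) for _ in range(n + 1)]
    move = [[0] * (m + 1) for _ in range(n + 1)]  # 1=skip a, 2=skip b, 3=match
    dp[0][0] = (0, 0.0)
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            best, mv = NEG, 0
            if i > 0 and dp[i - 1][j] > best:
                best, mv = dp[i - 1][j], 1
            if j > 0 and dp[i][j - 1] > best:
                best, mv = dp[i][j - 1], 2
            if i > 0 and j > 0:
                delta = abs(ta[i - 1] - tb[j - 1])
                if delta <= tolerance and dp[i - 1][j - 1] != NEG:
                    cand = (dp[i - 1][j - 1][0] + 1, dp[i - 1][j - 1][1] - delta)
                    if cand > best:
                        best, mv = cand, 3
            dp[i][j], move[i][j] = best, mv
    pairs = []
    i, j = n, m
    while i > 0 or j > 0:
        mv = move[i][j]
        if mv == 3:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif mv == 1:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    matched_a = {i for i, _ in pairs}
    matched_b = {j for _, j in pairs}
    return PeakMatching(
        pairs=tuple(pairs),
        unmatched_a=tuple(i for i in range(n) if i not in matched_a),
        unmatched_b=tuple(j for j in range(m) if j not in matched_b),
        total_abs_delta=float(sum(abs(ta[i] - tb[j]) for i, j in pairs)),
    )


def fingerprint_distance(
    a: MeltFingerprint,
    b: MeltFingerprint,
    tolerance: float = DEFAULT_TOLERANCE,
    unmatched_penalty: float = DEFAULT_UNMATCHED_PENALTY,
) -> float:
    """Bounded dissimilarity between two fingerprints (see module docstring)."""
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if not a.peaks and not b.peaks:
        raise ValueError("invalid fingerprints: both peak lists are empty")
    m = align_peak_lists(a, b, tolerance)
    u = m.n_unmatched
    return (m.total_abs_delta / tolerance + unmatched_penalty * u) / (m.n_matched + u)


@dataclass(frozen=True)
class ReferenceLibrary:
    """Archived consensus fingerprints: (species, primer) → MeltFingerprint."""

    species: tuple[str, ...]
    primers: tuple[str, ...]
    fingerprints: dict[tuple[str, str], MeltFingerprint]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (sp, pr), fp in self.fingerprints.items():
            if not fp.valid:
                raise ValueError(f"library fingerprint ({sp!r}, {pr!r}) has no peaks")
        for sp in self.species:
            if not any(k[0] == sp for k in self.fingerprints):
                raise ValueError(f"species {sp!r} has no fingerprint in the library")

    def get(self, species: str, primer: str) -> MeltFingerprint:
        return self.fingerprints[(species, primer)]

    def has(self, species: str, primer: str) -> bool:
        return (species, primer) in self.fingerprints


def _consensus_peaks(
    replicates: Sequence[MeltFingerprint],
    tolerance: float,
    min_replicate_support: float,
    label: str,
) -> tuple[MeltPeak, ...]:
    """Median-Tm consensus by tolerance linkage over pooled replicate peaks.

    Pooled peaks are sorted by Tm and split into clusters wherever the gap
    to the previous peak exceeds the tolerance; a cluster survives if it is
    supported by >= min_replicate_support of the replicates. A replicate
    contributing two peaks to one cluster is logged (each pooled peak stays
    with its nearest cluster by construction).
    """
    pooled = sorted(
        (p.tm, rep_idx, p)
        for rep_idx, fp in enumerate(replicates)
        for p in fp.peaks
    )
    if not pooled:
        return ()
    clusters: list[list[tuple[float, int, MeltPeak]]] = [[pooled[0]]]
    for item in pooled[1:]:
        if item[0] - clusters[-1][-1][0] > tolerance:
            clusters.append([item])
        else:
            clusters.append(clusters.pop() + [item])
    n_rep = len(replicates)
    out = []
    for cl in clusters:
        reps = {rep for _, rep, _ in cl}
        if len(reps) < len(cl):
            logger.debug("%s: replicate contributed two peaks to one consensus "
                         "group near %.2f °C", label, cl[0][0])
        if len(reps) / n_rep < min_replicate_support - 1e-12:
            continue
        tms = [tm for tm, _, _ in cl]
        out.append(MeltPeak(
            tm=float(np.median(tms)),
            height=float(np.median([p.height for _, _, p in cl])),
            prominence=float(np.median([p.prominence for _, _, p in cl])),
            width=float(np.median([p.width for _, _, p in cl])),
        ))
    return tuple(sorted(out, key=lambda p: p.tm))


def build_reference_library(
    replicate_fingerprints: Mapping[tuple[str, str], Sequence[MeltFingerprint]],
    min_replicate_support: float = 0.5,
    tolerance: float = DEFAULT_TOLERANCE,
    meta: Optional[dict] = None,
) -> ReferenceLibrary:
    """Consensus library from labeled replicate fingerprints.

    Consensus peak Tm is the median over the replicate peaks grouped by
    tolerance linkage; a peak group present in fewer than
    ``min_replicate_support`` of the replicates is dropped.
    """
    fingerprints = {}
    for (sp, pr), reps in replicate_fingerprints.items():
        if not reps:
            raise ValueError(f"no replicates for ({sp!r}, {pr!r})")
        peaks = _consensus_peaks(list(reps), tolerance, min_replicate_support,
                                 f"({sp}, {pr})")
        if not peaks:
            raise ValueError(
                f"consensus for ({sp!r}, {pr!r}) has no supported peaks"
            )
        fingerprints[(sp, pr)] = MeltFingerprint(
            primer=pr, peaks=peaks, source_id=f"consensus:{sp}"
        )
    species = tuple(sorted({sp for sp, _ in fingerprints}))
    primers = tuple(sorted({pr for _, pr in fingerprints}))
    return ReferenceLibrary(species=species, primers=primers,
                            fingerprints=fingerprints, meta=meta or {})


@dataclass(frozen=True)
class ClassificationResult:
    """Assignment of one query against the library."""

    query_id: str
    primer_set: tuple[str, ...]
    label: str
    best_distance: float
    margin: float
    per_primer_distances: dict[str, dict[str, float]]
    tie: bool = False
    reason: str = ""


def _assign(
    query_id: str,
    primer_set: tuple[str, ...],
    scores: Mapping[str, float],
    per_primer: dict[str, dict[str, float]],
    reject_threshold: float,
) -> ClassificationResult:
    ranked = sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))
    best_sp, best_d = ranked[0]
    margin = (ranked[1][1] - best_d) if len(ranked) > 1 else float("inf")
    tie = len(ranked) > 1 and abs(ranked[1][1] - best_d) < 1e-12
    if best_d > reject_threshold:
        return ClassificationResult(query_id, primer_set, UNCLASSIFIED, best_d,
                                    margin, per_primer, tie,
                                    reason="best distance above reject threshold")
    return ClassificationResult(query_id, primer_set, best_sp, best_d,
                                margin, per_primer, tie)


def classify_single_primer(
    query: MeltFingerprint,
    lib: ReferenceLibrary,
    primer: str,
    tolerance: float = DEFAULT_TOLERANCE,
    reject_threshold: float = DEFAULT_REJECT_THRESHOLD,
    unmatched_penalty: float = DEFAULT_UNMATCHED_PENALTY,
) -> ClassificationResult:
    """Nearest-reference assignment using one primer's fingerprint."""
    if primer not in lib.primers:
        raise ValueError(f"primer {primer!r} not in library")
    if not query.valid:
        return ClassificationResult(query.source_id, (primer,), UNCLASSIFIED,
                                    float("nan"), 0.0, {}, reason="invalid fingerprint")
    dists = {
        sp: fingerprint_distance(query, lib.get(sp, primer), tolerance,
                                 unmatched_penalty)
        for sp in lib.species if lib.has(sp, primer)
    }
    return _assign(query.source_id, (primer,), dists, {primer: dists},
                   reject_threshold)


def classify_combined(
    queries: Mapping[str, MeltFingerprint],
    lib: ReferenceLibrary,
    primer_set: Sequence[str],
    tolerance: float = DEFAULT_TOLERANCE,
    reject_threshold: float = DEFAULT_REJECT_THRESHOLD,
    unmatched_penalty: float = DEFAULT_UNMATCHED_PENALTY,
) -> ClassificationResult:
    """Assignment by the mean per-primer distance over a primer combination.

    The mean (not the sum) keeps the reject threshold scale-free in the
    number of primers.
    """
    missing = [p for p in primer_set if p not in queries]
    if missing:
        raise ValueError(f"no query fingerprint for primers: {missing}")
    primer_set = tuple(primer_set)
    qid = next((queries[p].source_id for p in primer_set if queries[p].source_id), "")
    usable = [p for p in primer_set if queries[p].valid]
    if not usable:
        return ClassificationResult(qid, primer_set, UNCLASSIFIED, float("nan"),
                                    0.0, {}, reason="invalid fingerprint")
    per_primer: dict[str, dict[str, float]] = {}
    for p in usable:
        per_primer[p] = {
            sp: fingerprint_distance(queries[p], lib.get(sp, p), tolerance,
                                     unmatched_penalty)
            for sp in lib.species if lib.has(sp, p)
        }
    species = set.intersection(*(set(d) for d in per_primer.values()))
    scores = {sp: float(np.mean([per_primer[p][sp] for p in usable]))
              for sp in species}
    return _assign(qid, primer_set, scores, per_primer, reject_threshold)


@dataclass(frozen=True)
class DiscriminationMatrix:
    """Pairwise species distinguishability under one primer set.

    A pair (s, t) is distinguishable if some primer in the set separates
    their consensus fingerprints by more than the uniqueness threshold.
    ``success_rate_species`` is the percentage of species distinguishable
    from *every* other species; ``success_rate_pairs`` the percentage of
    distinguishable pairs.
    """

    primer_set: tuple[str, ...]
    species: tuple[str, ...]
    distinguishable: dict[frozenset, bool]

    def is_distinguishable(self, s: str, t: str) -> bool:
        return self.distinguishable[frozenset((s, t))]

    @property
    def success_rate_species(self) -> float:
        ok = sum(
            all(self.is_distinguishable(s, t) for t in self.species if t != s)
            for s in self.species
        )
        return 100.0 * ok / len(self.species)

    @property
    def success_rate_pairs(self) -> float:
        vals = list(self.distinguishable.values())
        return 100.0 * sum(vals) / len(vals)


def discrimination_matrix(
    lib: ReferenceLibrary,
    primer_sets: Sequence[Sequence[str]],
    uniqueness_threshold: float = DEFAULT_UNIQUENESS_THRESHOLD,
    tolerance: float = DEFAULT_TOLERANCE,
    unmatched_penalty: float = DEFAULT_UNMATCHED_PENALTY,
) -> list[DiscriminationMatrix]:
    """One distinguishability matrix per primer set, from library references."""
    out = []
    for pset in primer_sets:
        pset = tuple(pset)
        for p in pset:
            for sp in lib.species:
                if not lib.has(sp, p):
                    raise ValueError(f"library lacks ({sp!r}, {p!r})")
        dist = {}
        for s, t in itertools.combinations(lib.species, 2):
            dist[frozenset((s, t))] = any(
                fingerprint_distance(lib.get(s, p), lib.get(t, p), tolerance,
                                     unmatched_penalty) > uniqueness_threshold
                for p in pset
            )
        out.append(DiscriminationMatrix(primer_set=pset, species=lib.species,
                                        distinguishable=dist))
    return out
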
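"""Synthetic melt panels and raw melt curves.

The generator emulates the statistical structure of a multi-species
ISSR-HRM experiment: each (species, primer) cell owns a small set of melt
transitions (one per resolvable amplicon population); raw curves are a sum
of logistic (two-state) melt sigmoids on a baseline with instrument noise;
replicates of one sample jitter every transition temperature independently
(Normal, ~0.1 °C); and geographic populations of one species may shift or
replace a cell's transitions.

Everything is a pure function of its spec and seed: sub-seeds are derived by
stable hashing of (master seed, role, species, primer, replicate), so adding
a species or primer does not perturb existing cells.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.special import expit

from . import study
from .grid import DEFAULT_GRID, TemperatureGrid
from .processing import MeltCurve

__all__ = [
    "TransitionSpec",
    "PanelSpec",
    "CurveRecord",
    "LabeledCurveSet",
    "subseed",
    "make_default_panel",
    "simulate_melt_curve",
    "generate_reference_curves",
    "generate_query_set",
]

#: Minimum Tm separation between transitions of one cell (°C): closer
#: transitions would merge into one derivative peak at typical widths.
MIN_TM_SEPARATION = 0.8

#: Pre-melt plateau (a.u.) of a default synthetic curve; the post-melt
#: plateau and the per-peak amplitudes are derived from it.
BASELINE_PRE_LEVEL = 100.0
BASELINE_POST_LEVEL = 5.0
BASELINE_SLOPE = -0.05

#: Default transition width (logistic scale, °C). Two logistic-derivative
#: peaks stay bimodal only when separated by roughly 3x their scale plus
#: the smoothing window, so the default is narrow enough that peaks at the
#: 0.8 °C separation floor remain resolvable after smoothing.
DEFAULT_WIDTH = 0.15


def subseed(master: int, *parts: object) -> int:
    """A stable 31-bit sub-seed from a master seed and a label path."""
    key = "|".join(str(p) for p in (master, *parts))
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass(frozen=True)
class TransitionSpec:
    """One melt transition: a logistic step of ``amplitude`` centred at ``tm``.

    ``width`` is the logistic scale in °C; the derivative peak it produces
    has height amplitude/(4·width).
    """

    tm: float
    amplitude: float
    width: float = DEFAULT_WIDTH

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError(f"transition amplitude must be > 0, got {self.amplitude}")
        if self.width <= 0:
            raise ValueError(f"transition width must be > 0, got {self.width}")


def _check_separations(tms: Sequence[float], label: str) -> None:
    s = sorted(tms)
    for a, b in zip(s, s[1:]):
        if b - a < MIN_TM_SEPARATION - 1e-9:
            raise ValueError(
                f"{label}: transitions at {a:.2f} and {b:.2f} °C are closer "
                f"than {MIN_TM_SEPARATION} °C"
            )


@dataclass(frozen=True)
class PanelSpec:
    """Ground-truth melt panel: species × primer → transition lists.

    ``population_offsets`` maps (species, population) to per-primer,
    per-peak °C shifts; ``population_overrides`` maps
    (species, population, primer) to a full replacement transition list for
    cells where a population differs in peak count, not just position.
    """

    species: tuple[str, ...]
    primers: tuple[str, ...]
    transitions: dict[tuple[str, str], tuple[TransitionSpec, ...]]
    tm_jitter_sd: float = 0.1
    amplitude_jitter_cv: float = 0.05
    noise_sd: float = 0.2
    baseline_pre_level: float = BASELINE_PRE_LEVEL
    baseline_post_level: float = BASELINE_POST_LEVEL
    baseline_slope: float = BASELINE_SLOPE
    population_offsets: dict[tuple[str, str], dict[str, tuple[float, ...]]] = field(
        default_factory=dict
    )
    population_overrides: dict[tuple[str, str, str], tuple[TransitionSpec, ...]] = field(
        default_factory=dict
    )
    grid: TemperatureGrid = DEFAULT_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.tm_jitter_sd, self.amplitude_jitter_cv, self.noise_sd) < 0:
            raise ValueError("jitter and noise parameters must be >= 0")
        for sp in self.species:
            for pr in self.primers:
                cell = self.transitions.get((sp, pr))
                if cell is None:
                    raise ValueError(f"panel is missing cell ({sp!r}, {pr!r})")
                if not 1 <= len(cell) <= 8:
                    raise ValueError(
                        f"cell ({sp!r}, {pr!r}) must have 1–8 transitions, "
                        f"got {len(cell)}"
                    )
                _check_separations([t.tm for t in cell], f"cell ({sp!r}, {pr!r})")

    def resolve(
        self, species: str, primer: str, population: Optional[str] = None
    ) -> tuple[TransitionSpec, ...]:
        """Transition list for a cell, with population override/offsets applied."""
        if population is not None:
            override = self.population_overrides.get((species, population, primer))
            if override is not None:
                return override
        cell = self.transitions[(species, primer)]
        if population is not None:
            shifts = self.population_offsets.get((species, population), {}).get(primer)
            if shifts:
                cell = tuple(
                    replace(t, tm=t.tm + (shifts[i] if i < len(shifts) else 0.0))
                    for i, t in enumerate(cell)
                )
        return cell

    def tm_list(self, species: str, primer: str, population: Optional[str] = None) -> tuple[float, ...]:
        return tuple(t.tm for t in self.resolve(species, primer, population))

    # -- serialization ----------------------------------------------------

    def to_json(self) -> dict:
        return {
            "schema": "meltfp-panel-v1",
            "species": list(self.species),
            "primers": list(self.primers),
            "transitions": {
                f"{sp}\t{pr}": [[t.tm, t.amplitude, t.width] for t in cell]
                for (sp, pr), cell in sorted(self.transitions.items())
            },
            "tm_jitter_sd": self.tm_jitter_sd,
            "amplitude_jitter_cv": self.amplitude_jitter_cv,
            "noise_sd": self.noise_sd,
            "baseline_pre_level": self.baseline_pre_level,
            "baseline_post_level": self.baseline_post_level,
            "baseline_slope": self.baseline_slope,
            "population_offsets": {
                f"{sp}\t{pop}": {pr: list(sh) for pr, sh in offs.items()}
                for (sp, pop), offs in sorted(self.population_offsets.items())
            },
            "population_overrides": {
                f"{sp}\t{pop}\t{pr}": [[t.tm, t.amplitude, t.width] for t in cell]
                for (sp, pop, pr), cell in sorted(self.population_overrides.items())
            },
            "grid": [self.grid.start, self.grid.stop, self.grid.step],
            "seed": self.seed,
        }

    @classmethod
    def from_json(cls, doc: Mapping) -> "PanelSpec":
        if doc.get("schema") != "meltfp-panel-v1":
            raise ValueError(f"unknown panel schema {doc.get('schema')!r}")

        def cell(v: Iterable) -> tuple[TransitionSpec, ...]:
            return tuple(TransitionSpec(tm=a, amplitude=b, width=c) for a, b, c in v)

        return cls(
            species=tuple(doc["species"]),
            primers=tuple(doc["primers"]),
            transitions={
                tuple(k.split("\t")): cell(v) for k, v in doc["transitions"].items()
            },
            tm_jitter_sd=float(doc["tm_jitter_sd"]),
            amplitude_jitter_cv=float(doc["amplitude_jitter_cv"]),
            noise_sd=float(doc["noise_sd"]),
            baseline_pre_level=float(doc["baseline_pre_level"]),
            baseline_post_level=float(doc["baseline_post_level"]),
            baseline_slope=float(doc["baseline_slope"]),
            population_offsets={
                tuple(k.split("\t")): {pr: tuple(sh) for pr, sh in v.items()}
                for k, v in doc.get("population_offsets", {}).items()
            },
            population_overrides={
                tuple(k.split("\t")): cell(v)
                for k, v in doc.get("population_overrides", {}).items()
            },
            grid=TemperatureGrid(*doc["grid"]),
            seed=int(doc["seed"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "PanelSpec":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


@dataclass(frozen=True)
class CurveRecord:
    """One labeled raw curve: the ground truth behind a well."""

    curve: MeltCurve
    species: str
    population: Optional[str] = None
    replicate_id: str = ""


@dataclass(frozen=True)
class LabeledCurveSet:
    """A set of labeled curves sharing one temperature grid."""

    records: tuple[CurveRecord, ...]
    grid: TemperatureGrid = DEFAULT_GRID

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def for_primer(self, primer: str) -> tuple[CurveRecord, ...]:
        return tuple(r for r in self.records if r.curve.primer == primer)


def _transition_amplitudes(n_peaks: int, pre: float, post: float) -> float:
    """Equal per-peak amplitude so the curve spans the pre→post range."""
    return (pre - post) / n_peaks


def _random_cell(
    rng: np.random.Generator,
    pre: float,
    post: float,
    lo: float = 75.0,
    hi: float = 90.0,
) -> tuple[TransitionSpec, ...]:
    """2–5 random transitions in [lo, hi] °C respecting the separation rule."""
    k = int(rng.integers(2, 6))
    for _ in range(1000):
        tms = np.sort(rng.uniform(lo, hi, size=k))
        if np.all(np.diff(tms) >= MIN_TM_SEPARATION):
            amp = _transition_amplitudes(k, pre, post)
            return tuple(TransitionSpec(tm=float(t), amplitude=amp) for t in tms)
    raise RuntimeError("rejection sampling failed (separation rule)")  # pragma: no cover


#: First Kogia melting peak, not printed in the published fingerprints:
#: planted at a shared 78.0 °C for both Kogia species.
KOGIA_FIRST_PEAK = 78.0


def make_default_panel(seed: int = 0) -> PanelSpec:
    """The 16-species × 8-primer study panel.

    Cells whose melting-peak temperatures were published use exactly those
    values; every other cell is filled with 2–5 random transitions in
    [75, 90] °C, deterministically from ``seed``. The dugong base cell under
    UBC848 carries the Andaman Sea (AND) fingerprint; the Gulf of Thailand
    (GOT) population overrides it with its printed two-peak fingerprint and
    is shifted by small per-peak offsets under the remaining primers.
    """
    pre, post = BASELINE_PRE_LEVEL, BASELINE_POST_LEVEL
    printed = dict(study.PRINTED_FINGERPRINTS)
    printed[("Dwarf sperm whale", "UBC826")] = (
        KOGIA_FIRST_PEAK, *printed[("Dwarf sperm whale", "UBC826")]
    )
    printed[("Pygmy sperm whale", "UBC826")] = (
        KOGIA_FIRST_PEAK, *printed[("Pygmy sperm whale", "UBC826")]
    )

    transitions: dict[tuple[str, str], tuple[TransitionSpec, ...]] = {}
    for sp in study.SPECIES:
        for pr in study.PRIMERS:
            tms = printed.get((sp, pr))
            if tms is not None:
                amp = _transition_amplitudes(len(tms), pre, post)
                transitions[(sp, pr)] = tuple(
                    TransitionSpec(tm=t, amplitude=amp) for t in tms
                )
            else:
                rng = np.random.default_rng(subseed(seed, "cell", sp, pr))
                transitions[(sp, pr)] = _random_cell(rng, pre, post)

    got_amp = _transition_amplitudes(len(study.DUGONG_GOT_UBC848), pre, post)
    overrides = {
        ("Dugong", "GOT", "UBC848"): tuple(
            TransitionSpec(tm=t, amplitude=got_amp) for t in study.DUGONG_GOT_UBC848
        )
    }
    # GOT dugongs: +0.1 °C on every peak for the primers where the two
    # populations show the same pattern slightly shifted; a larger shift of
    # the first two peaks where the published comparison shows them moved.
    offsets: dict[str, tuple[float, ...]] = {}
    for pr in ("UBC812", "UBC818", "UBC827"):
        n = len(transitions[("Dugong", pr)])
        offsets[pr] = (0.1,) * n
    for pr in ("UBC817", "UBC826"):
        n = len(transitions[("Dugong", pr)])
        offsets[pr] = tuple([0.4, 0.3][:n]) + (0.0,) * max(0, n - 2)

    return PanelSpec(
        species=study.SPECIES,
        primers=study.PRIMERS,
        transitions=transitions,
        population_offsets={("Dugong", "GOT"): offsets},
        population_overrides=overrides,
        seed=seed,
    )


def simulate_melt_curve(
    transitions: Sequence[TransitionSpec],
    grid: TemperatureGrid = DEFAULT_GRID,
    noise_sd: float = 0.0,
    baseline_post_level: float = BASELINE_POST_LEVEL,
    baseline_slope: float = BASELINE_SLOPE,
    seed: Optional[int] = None,
    curve_id: str = "sim",
    primer: str = "NA",
) -> MeltCurve:
    """Synthesize one raw melt curve.

    F(T) = post + slope·(T − start) + Σᵢ aᵢ·logistic((tmᵢ − T)/wᵢ) + ε,
    ε ~ N(0, noise_sd²). With zero noise the curve is exactly reproducible
    from its parameters and non-increasing up to |slope|.
    """
    for t in transitions:
        if not grid.contains(t.tm, strict=True):
            raise ValueError(
                f"transition tm {t.tm} °C is not strictly inside the grid "
                f"({grid.start}, {grid.stop})"
            )
        if t.width < grid.step:
            raise ValueError(
                f"transition width {t.width} °C is below the grid step {grid.step}"
            )
    T = grid.temperatures()
    F = baseline_post_level + baseline_slope * (T - grid.start)
    for t in transitions:
        F = F + t.amplitude * expit((t.tm - T) / t.width)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        F = F + rng.normal(0.0, noise_sd, size=T.size)
    return MeltCurve(id=curve_id, primer=primer, temperatures=T, fluorescence=F)


def _jittered(
    cell: Sequence[TransitionSpec],
    rng: np.random.Generator,
    tm_sd: float,
    amp_cv: float,
    grid: TemperatureGrid,
) -> tuple[TransitionSpec, ...]:
    out = []
    for t in cell:
        tm = t.tm + (rng.normal(0.0, tm_sd) if tm_sd > 0 else 0.0)
        tm = float(np.clip(tm, grid.start + 1.0, grid.stop - 1.0))
        amp = t.amplitude * max(1e-3, 1.0 + (rng.normal(0.0, amp_cv) if amp_cv > 0 else 0.0))
        out.append(TransitionSpec(tm=tm, amplitude=amp, width=t.width))
    return tuple(out)


def generate_reference_curves(
    panel: PanelSpec,
    replicates_per_cell: int = 3,
    population: Optional[str] = None,
) -> LabeledCurveSet:
    """Replicate curves for every (species, primer) cell of the panel.

    Per-replicate Tm jitter ~ N(0, tm_jitter_sd²) is applied independently
    per peak before curve synthesis; amplitudes get multiplicative jitter
    with CV ``amplitude_jitter_cv``; instrument noise uses ``noise_sd``.
    """
    if replicates_per_cell < 1:
        raise ValueError("replicates_per_cell must be >= 1")
    records = []
    for sp in panel.species:
        for pr in panel.primers:
            cell = panel.resolve(sp, pr, population)
            for rep in range(replicates_per_cell):
                rng = np.random.default_rng(
                    np.random.SeedSequence(subseed(panel.seed, "ref", sp, pr, rep))
                )
                jit = _jittered(cell, rng, panel.tm_jitter_sd,
                                panel.amplitude_jitter_cv, panel.grid)
                cid = f"{sp}|{pr}|r{rep}"
                curve = simulate_melt_curve(
                    jit, panel.grid, noise_sd=0.0,
                    baseline_post_level=panel.baseline_post_level,
                    baseline_slope=panel.baseline_slope,
                    curve_id=cid, primer=pr,
                )
                if panel.noise_sd > 0:
                    F = curve.fluorescence + rng.normal(
                        0.0, panel.noise_sd, size=curve.temperatures.size
                    )
                    curve = MeltCurve(id=cid, primer=pr,
                                      temperatures=curve.temperatures, fluorescence=F)
                records.append(CurveRecord(curve=curve, species=sp,
                                           population=population,
                                           replicate_id=f"r{rep}"))
    return LabeledCurveSet(records=tuple(records), grid=panel.grid)


def generate_query_set(
    panel: PanelSpec,
    counts: Optional[Mapping[str, int]] = None,
    tm_jitter_sd: Optional[float] = None,
    noise_sd: Optional[float] = None,
    seed: Optional[int] = None,
    populations: Optional[Mapping[str, str]] = None,
) -> LabeledCurveSet:
    """Labeled blind-trial queries: ``counts[species]`` individuals, each
    yielding one curve per panel primer.

    Defaults reproduce the study's query design: 31/30/28/27/24 individuals
    over the five reference species (140 per primer). ``populations``
    optionally assigns a population tag (and its offsets) per species.
    """
    if counts is None:
        counts = study.QUERY_COUNTS
    unknown = set(counts) - set(panel.species)
    if unknown:
        raise ValueError(f"query species not in panel: {sorted(unknown)}")
    if any(n < 0 for n in counts.values()):
        raise ValueError("query counts must be >= 0")
    tm_sd = panel.tm_jitter_sd if tm_jitter_sd is None else tm_jitter_sd
    nz = panel.noise_sd if noise_sd is None else noise_sd
    master = panel.seed if seed is None else seed
    records = []
    for sp in counts:
        pop = populations.get(sp) if populations else None
        for i in range(counts[sp]):
            qid = f"q|{sp}|{i}"
            for pr in panel.primers:
                rng = np.random.default_rng(
                    np.random.SeedSequence(subseed(master, "query", sp, i, pr))
                )
                cell = panel.resolve(sp, pr, pop)
                jit = _jittered(cell, rng, tm_sd, panel.amplitude_jitter_cv, panel.grid)
                curve = simulate_melt_curve(
                    jit, panel.grid, noise_sd=0.0,
                    baseline_post_level=panel.baseline_post_level,
                    baseline_slope=panel.baseline_slope,
                    curve_id=f"{qid}|{pr}", primer=pr,
                )
                if nz > 0:
                    F = curve.fluorescence + rng.normal(0.0, nz, size=curve.temperatures.size)
                    curve = MeltCurve(id=f"{qid}|{pr}", primer=pr,
                                      temperatures=curve.temperatures, fluorescence=F)
                records.append(CurveRecord(curve=curve, species=sp,
                                           population=pop, replicate_id=qid))
    return LabeledCurveSet(records=tuple(records), grid=panel.grid)
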
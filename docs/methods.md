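# Methods

## The melt-curve model

Each (species, primer) cell of a panel owns 1–8 **melt transitions**, one
per resolvable amplicon population. A raw curve is

    F(T) = b_post + s·(T − T_start) + Σᵢ aᵢ · σ((Tmᵢ − T) / wᵢ) + ε,

with σ the logistic function and ε ~ N(0, noise_sd²) i.i.d. per grid
point. The logistic step is the standard two-state (helix→coil)
approximation of a single duplex population melting; its negative
derivative is a symmetric peak of height aᵢ/(4wᵢ) centred exactly at Tmᵢ,
which gives every downstream stage a closed form to test against. The
default acquisition grid is 55–95 °C in 0.1 °C increments (401 points),
matching a standard HRM ramp.

Defaults (all configurable on `PanelSpec` / `TransitionSpec`):

| parameter | default | units | rationale |
|---|---|---|---|
| pre-melt plateau | 100 | a.u. | arbitrary instrument scale |
| post-melt plateau | 5 | a.u. | residual dye signal |
| baseline drift | −0.05 | a.u./°C | slight photobleaching-like slope |
| transition width w | 0.15 | °C | see "resolvability" below |
| per-peak amplitude | (100−5)/k | a.u. | equal split over the k peaks of a cell |
| replicate Tm jitter | 0.1 | °C | shifts of 0.1 °C are treated as real between runs |
| amplitude jitter CV | 0.05 | — | pipetting/template-amount variation |
| instrument noise | 0.2 | a.u. | ~0.2% of dynamic range |
| within-cell Tm separation | ≥ 0.8 | °C | closer transitions are one peak in practice |

**Resolvability.** Two equal logistic-derivative peaks separated by s
merge into a single maximum unless s ≳ 3.2·w, and the smoothing filter
(below) adds its own blur. With w = 0.4 °C — a natural-looking first
choice — peaks at the panel's own 0.8 °C separation floor collapse into
one, breaking the zero-noise round trip. The defaults w = 0.15 °C and a
1.3 °C smoothing window were chosen (once, jointly) so that 0.8 °C-
separated transitions are recovered within ±0.05 °C while a noise-only
curve at the default noise level produces no called peaks (0/300 seeds).

## The default 16 × 8 panel

Species and primers follow the marine-mammal reference design: 16 species
(five of them — spinner, striped, pantropical spotted, bottlenose
dolphin, dugong — with blind-query cohorts of 31/30/28/27/24, total 140)
and the 8 UBC ISSR primers. Cells whose melting-peak temperatures are
published are planted verbatim: bottlenose × UBC812 (80.0, 81.9, 86.1,
88.0 °C), striped × UBC812 (79.9, 82.1, 86.1, 88.0), dugong × UBC848
(Andaman Sea: 79.9, 82.6, 87.7; Gulf of Thailand: 80.5, 82.6), and the
two *Kogia* species × UBC826. The *Kogia* first peak is not published
(only the 2nd/3rd/4th); a shared 78.0 °C first transition is planted for
both, mimicking their near-identical patterns. All other cells are filled
with 2–5 uniform-random transitions in [75, 90] °C, rejection-sampled to
the 0.8 °C separation rule, deterministically per (seed, species, primer)
via stable SHA-256 sub-seeding — adding a species or primer does not
perturb existing cells.

Dugong populations are modelled two ways: per-peak Tm **offsets**
(+0.1 °C under UBC812/UBC818/UBC827, larger first/second-peak shifts
under UBC817/UBC826, values chosen once as plausible emulations of the
reported population differences) and a full **override** for UBC848,
where the Gulf-of-Thailand population has a different peak count and
offsets cannot express that.

## Extraction

1. **Normalization** — affine map sending the mean over a pre-melt window
   to 1 and the mean over a post-melt window to 0. The windows are not
   standardized by HRM vendors; the defaults are the first and last 2 °C
   of the grid, overridable per curve. A curve whose two means coincide is
   rejected as degenerate rather than amplified into garbage.
2. **Derivative** — Savitzky–Golay first derivative, polynomial order 3,
   window 1.3 °C (13 points), negated; raw finite differences at 0.1 °C
   amplify noise ~50-fold. The filter's half-window is trimmed at each
   end. The apex attenuation this causes (&lt;1% at w = 0.4 °C, ~15% at the
   default w = 0.15 °C) affects peak heights only, never positions.
3. **Peak calling** — `scipy.signal.find_peaks` with prominence ≥ 5% of
   the derivative maximum, absolute height ≥ 0.02 /°C, minimum separation
   0.8 °C. The absolute height floor is what rejects noise-only curves
   (their derivative extremes stay below ~0.01 /°C at default noise); the
   relative prominence floor prunes shoulder artifacts on real peaks. Tm
   is refined by a parabola through the three points around each maximum;
   flat-topped maxima keep their leftmost grid point. Zero-peak
   fingerprints are returned flagged invalid, not raised.

Peak-calling thresholds of the instrument software are unpublished; these
defaults are this package's own and all sit in `ProcessingConfig`.

## Matching and classification

Fingerprints are compared by a **monotone one-to-one alignment** of their
sorted Tm lists: crossing matches are physically meaningless for peaks
ordered by temperature. Among alignments whose pairs agree within a
tolerance (default 0.3 °C — replicate scatter is ~0.1 °C, within-pattern
peaks ≥ 0.8 °C apart, so 0.3 splits the difference), the DP maximizes the
matched-pair count, then minimizes Σ|ΔTm|. Tests verify equivalence with
exhaustive enumeration over all monotone matchings and with an
unrestricted optimal assignment (which has a non-crossing optimum on
sorted lists). The alignment is summarized as

    d = (Σ_matched |ΔTm|/tol + λ·u) / (n_matched + u),   λ = 1 default,

a symmetric dissimilarity in [0, λ], zero iff the patterns match exactly.
A query is assigned to the argmin-distance species; ties break
lexicographically and are flagged; a best distance above the reject
threshold (default 0.5) yields UNCLASSIFIED. Primer combinations score
each species by the **mean** per-primer distance, keeping the reject
threshold scale-free in the number of primers. Reference consensus is the
median Tm over replicate peaks grouped by tolerance linkage, keeping
groups present in ≥ 50% of replicates. Peak heights are carried as
metadata but never enter the distance — whether human judges used them is
unknown, so the conservative choice is not to.

Two species are **distinguishable** under a primer set if some primer
separates their consensus fingerprints by more than the uniqueness
threshold (default 0.25). The discrimination success rate is reported
both per species (% of species distinguishable from *every* other — the
primary reading) and per pair (% of distinguishable pairs), since the
published heatmap's exact definition is ambiguous. Distinguishability is
monotone under primer-set inclusion by construction.

## Evaluation

One-vs-rest 2×2 counts per (primer, target species): TP = called target
and is target; FP = called target, is other; FN = is target, called
other *or UNCLASSIFIED*; TN = the rest. Metrics with zero denominator are
reported as NA — never coerced to 0 — and skipped (and flagged) in means.
Aggregation follows the published table shapes: per-primer rows with a
mean column over the five query species, and per-species means over the
8 primers; means are computed on unrounded values, with decimal half-up
rounding to two decimals applied only at presentation. The published
per-cell percentages (from blind human judging of real curves) are
shipped as fixed inputs in `meltfp.study`; only their aggregation is
recomputed, and it reproduces every published mean to within half the
printed precision (one mean, 92.095, sits exactly on the rounding
boundary and prints one ulp low).

`run_blind_trial` chains the whole pipeline — panel → replicate reference
curves → consensus library → 140 labeled queries → extraction →
per-primer classification → tables and discrimination matrices — and is
bit-reproducible from one seed.

## What the generator does and does not emulate

It reproduces the *statistical structure* the analysis assumes:
multi-peak patterns, replicate Tm scatter, population shifts, baseline
and noise. It does not model amplicon sequences or thermodynamic Tm
prediction, plate-position effects, inter-run calibration drift, primer
dropout, or the within-species biological variability that made real
Delphinidae fingerprints hard to judge — random cells separate species
more cleanly than real curves do. Passing tests therefore demonstrate the
correctness and calibration of the *pipeline*, not field-accuracy claims:
zero-noise trials hit 100% on all metrics by construction of a separable
panel, and accuracy degrades monotonically as Tm jitter grows past the
matching tolerance, with rejection (UNCLASSIFIED) the dominant failure
mode at jitter ≥ 0.2 °C.

## Problem sizes in tests and the acceptance script

The blind trials use the study design verbatim (140 queries × 8 primers,
3 replicates per reference cell). Monte-Carlo sweeps use panels
restricted to the five query species with 3 queries per species:
20 seeds × 4 jitter levels {0, 0.2, 0.5, 1.0} °C for the degradation
check, 10 paired seeds for the combined-vs-single-primer comparison, and
500–1000 random cases for the DP and confusion-matrix oracle checks.
These sizes keep the full suite under half a minute while leaving the
statistical conclusions unambiguous.

## Known limitations

* Heights/prominences are attenuated by smoothing (reported, not
  corrected); analyses must not read absolute peak heights as amplitudes.
* Overlapping transitions closer than ~0.8 °C are deliberately out of
  scope (the panel invariant forbids them); real mixtures can contain
  them and would merge.
* The reject/uniqueness/λ thresholds quantify a judgment the original
  workflow made visually; their defaults are package choices exposed as
  config keys, not published values.
* Tm is reported at full interpolated precision internally and rounded
  to 0.1 °C only in reports and serialization (4 decimals in JSON).
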
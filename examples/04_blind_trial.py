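"""The full simulated double-blind identification trial.

Reproduces the study's query design — 31/30/28/27/24 blind individuals over
the five reference species, 140 in total, each melted with all 8 primers —
under realistic replicate jitter and noise, then prints the per-primer and
per-species metric tables.
"""

from meltfp import TrialConfig, run_blind_trial

trial = run_blind_trial(TrialConfig(seed=1, replicates=3))

print(f"queries evaluated: {trial.n_queries}")
print("\nper-primer one-vs-rest metrics (%, mean over species):")
print(trial.metrics.rounded().per_primer["Mean"].unstack(level="metric"))
print("\nper-species means over the 8 primers (%):")
print(trial.metrics.rounded().per_species)
print("\nplain assignment accuracy per primer:")
for primer in trial.results:
    print(f"  {primer}: {100 * trial.accuracy_of(primer):5.1f}%")
# One-vs-rest accuracy is high even when assignment accuracy is ~85%
# because every query that is *not* the target species and is not called as
# it counts as a true negative.
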
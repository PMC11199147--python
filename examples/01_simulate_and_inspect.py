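"""Simulate a word-production session and inspect its structure.

Builds a population of word-selective units, simulates one session of the
eight-word task (6 lexical words + 2 pseudowords, six phases per trial),
writes it to an HDF5 archive and reads it back.
"""

import tempfile
from pathlib import Path

import innerspeech as isp

config = isp.TaskConfig()
print(f"words: {', '.join(config.words)}")
print(f"phases: {dict(zip(config.phase_names, config.phase_durations))} (s)")

population = isp.sample_population(isp.PopulationSpec(n_units=16, seed=0), config)
trials, spikes, ground_truth = isp.simulate_session(
    population, config, n_reps=8, cue_modalities=("written",), seed=1
)
print(f"\nsimulated {len(trials)} trials ({config.n_words} words x 8 repetitions)")
counts = isp.repetition_counts(trials)
print(f"repetitions per word: {sorted(set(counts['n_reps']))}")

n_tuned = sum(1 for u in population if u.tuned_phases())
print(f"{n_tuned}/{len(population)} units carry word-selective gain (ground truth)")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "session.h5"
    isp.write_session(path, config, trials, spikes, ground_truth=ground_truth)
    config2, trials2, spikes2, gt2 = isp.read_session(path)
    same = trials2.equals(trials) and all(
        (spikes2.trains[k] == v).all() for k, v in spikes.trains.items()
    )
    print(f"archive round trip identical: {same}")

# A session with behavioural errors: flagged trials stay in the archive and
# are removed only at analysis time.
with_errors = isp.inject_errors(trials, p_spoke_during_internal=0.05, seed=2)
clean, _, report = isp.exclude_error_trials(with_errors, spikes)
print(f"\nerror handling: {report['n_input']} trials -> {report['n_retained']} "
      f"retained, excluded by kind: {report['excluded']}")
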
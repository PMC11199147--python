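"""Demixed PCA: split population variance into timing, cue and word parts.

The balanced trial tensor is decomposed exactly into marginalizations
(condition-independent timing, cue modality, word identity, their
interaction, and trial noise); a regularized encoder/decoder pair is fit
per marginalization with the ridge penalty chosen by tenfold CV.  A
word-selective (SMG-like) population is contrasted with a word-agnostic
speech-gain (S1-like) one.
"""

import numpy as np

import innerspeech as isp

config = isp.TaskConfig()


def session_tensor(area, seed):
    pop = isp.sample_population(
        isp.PopulationSpec(n_units=24, area=area, seed=seed), config
    )
    trials, spikes, _ = isp.simulate_session(
        pop, config, n_reps=8, cue_modalities=("auditory", "written"), seed=seed + 1
    )
    tensor = isp.smooth_rates(isp.bin_spike_counts(spikes, trials, config),
                              config.kernel_width)
    return isp.build_balanced_tensor(tensor, trials, config, k_target=8)


for area in ("SMG", "S1"):
    tt = session_tensor(area, seed=70 if area == "SMG" else 80)
    lam, cv_table = isp.select_lambda(tt, [1e-7, 1e-6, 1e-5, 1e-4], folds=10,
                                      seed=7, q=2)
    model = isp.fit_dpca(tt, lam=lam, q=2)
    ledger, projections = isp.variance_and_projections(model, tt)
    shares = ledger.drop_duplicates("marginalization").set_index("marginalization")
    print(f"\n{area}-like population (lambda* = {lam:g} by tenfold CV):")
    for name in ("timing", "cue", "word", "cue_word"):
        raw = 100 * shares.loc[name, "marg_variance_share"]
        sig = 100 * shares.loc[name, "signal_variance_share"]
        print(f"  {name:<9} raw {raw:5.1f}%   noise-floor-corrected signal {sig:5.1f}%")
    print(f"  noise     raw {100 * shares.loc['noise', 'marg_variance_share']:5.1f}%")
    top_word = projections["word"][0]  # (T, C, W) time course of component 1
    spread = top_word.std(axis=(1, 2)).max()
    print(f"  top word-component spread across words: {spread:.2f} (a.u.)")

print("\nReading: both areas show timing structure (rates rise in active")
print("phases), but only the word-selective population retains word variance")
print("after subtracting the trial-averaging noise floor - the word share of")
print("the speech-gain population is statistically zero.")
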
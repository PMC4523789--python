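"""How the adaptive search places stimuli for different response states.

Liberal observers (high false-alarm rate) force the method to spend trials
at very low contrasts: a Yes at low intensity could signal either a low
threshold or a liberal criterion, and only null-region sampling separates
the two. The cumulative histograms below show the liberal state receiving
several times more sub-5%-contrast presentations than the conservative one.
"""

import quicksdt as q

study = q.run_study("qYN", n_reps=200, checkpoints=(25,), seed=3)
hist = q.stimulus_histograms(study, checkpoints=(25,))

print("fraction of the first 25 trials presented below 5% contrast:")
for state, sub in hist.groupby("state"):
    low = sub[sub["contrast"] < 0.05]["count"].sum() / sub["count"].sum()
    print(f"  {state:>10s}: {low:.1%}")

print("\nmedian presented contrast per state:")
for state, batch in study.batches.items():
    contrasts = batch.task.contrasts[batch.condition_idx.ravel()]
    import numpy as np

    print(f"  {state:>10s}: {np.median(contrasts):.1%}")
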
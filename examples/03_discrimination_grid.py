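"""The full comparison grid: measurement schemes x size treatments.

Runs one linear protocol and the full landmark configuration through raw,
isometry-free and allometry-free treatments; each cell is a PCA truncated at
95% cumulative variance followed by an equal-prior LDA with leave-one-out
posteriors, summarized by the membership-based performance measures.
Unidentified specimens are classified from the isometry-free cells.
"""

import numpy as np

import morphodisc as md

spec = md.SyntheticSpec(
    n_landmarks=40,
    groups=(
        md.GroupSpec("north", 30, 3.36, 0.05, 0.012, n_unknown=4),
        md.GroupSpec("south", 38, 3.39, 0.05, 0.012, n_unknown=4),
        md.GroupSpec("sub", 68, 3.42, 0.05, 0.012, n_unknown=4),
    ),
    allometry_coefficient=0.5,
    noise_sd=0.002,
    seed=8,
)
dataset, truth = md.generate(spec)
protocol = md.attach_protocol(spec, k_pairs=18, seed=3, name="linear18")

result = md.run_pipeline(dataset, {"linear18": protocol}, n_perm=499, seed=1)
table = md.report_table(result)
cols = ["scheme", "treatment", "CR", "AC", "AS", "CF", "allometry_R2", "n_retained_95"]
print(table[cols].round(3).to_string(index=False))
print(
    "\nCR = fraction of leave-one-out assignments that hit the true group;"
    "\nAC/AS = closeness of the posterior memberships to the truth/assignment"
    " indicators (1 perfect, 0 uninformative); CF = mean posterior of the"
    " assigned group."
)

hidden = np.array([g for g, h in zip(truth.groups, truth.is_unknown) if h])
preds = result.unknown_predictions["GMM"]
rate = np.mean(preds["predicted"].to_numpy() == hidden)
print(f"\nunknown specimens recovered by the GMM isometry-free model: "
      f"{rate:.0%} of {len(hidden)}")
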
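"""Classify samples in principal-component space, leave-one-out.

On a partially eroded cohort (lambda = 0.8) the case group separates
from controls along the unique-site axes.  Each sample is held out, the
PCA basis refit without it, and the sample projected and classified by
three distance models.  Low-variability control sites carry no disease
signal and should classify near chance.
"""

import episcape as ep

config = ep.SyntheticConfig(
    n_tissues=4, samples_per_tissue_per_group=20, n_sites=2000,
    n_unique_per_tissue=50, erosion_lambda=0.8, missing_rate=0.0, seed=19,
)
matrix, meta, truth = ep.generate_multitissue(config)

tissue = truth.unique_sites[0].tissue
ids = ep.samples_of(meta, tissue=tissue)
m, md = matrix.select_samples(ids), meta.loc[ids]
unique_ids = sorted(truth.unique_ids(tissue))

print(f"focal tissue: {tissue}, {len(ids)} samples, "
      f"{len(unique_ids)} unique sites")
for model in ep.MODELS:
    report = ep.loo_accuracy(m, md, unique_ids, ("control", "case"), model=model)
    print(f"  LOO accuracy [{model:9s}]: {report.accuracy:5.1f}%")

low = ep.select_control_sites(m, n=len(unique_ids), mode="low_variability",
                              exclude=truth.unique_ids())
acc_low = ep.loo_accuracy(m, md, low, ("control", "case"),
                          model="centroid").accuracy
print(f"  LOO accuracy [centroid] on low-variability control sites: "
      f"{acc_low:5.1f}%")
print("unique sites should beat the control sites by a wide margin: the"
      "\ndisease signal lives specifically in the tissue-unique signature.")
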
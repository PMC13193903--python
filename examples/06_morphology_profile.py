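"""Automatic morphology profiling of an unlabeled pool.

Labels every frame of a held-out pool with a trained classifier and
summarizes the predicted morphology composition per condition x season,
excluding the residual multiple-event and debris categories from the
biological denominators (they are tallied separately).
"""

import ifcmorph as im
from ifcmorph.data import ImageDataset
from ifcmorph.reporting import profile_pool, profile_report_markdown

h = im.HierarchySpec(
    n_bulls=6, ejaculates_per_bull={"fresh": 2, "frozen": 1},
    files_per_ejaculate=2, events_per_file=400, seed=5,
)
doms = im.default_domains()
manifest = im.generate_dataset(h, doms)
pool = im.quota_sample(manifest, im.QuotaSpec(per_stratum_quota=10), rng_seed=1)
train, val, test = im.stratified_split(pool, im.SplitSpec(seed=0))
ds = ImageDataset(pool, doms)
ds.stem_array()

model = im.train(
    (ds.subset(train), ds.subset(val)),
    im.TrainConfig(regime="LP_FT", max_epochs_lp=30, max_epochs_ft=8,
                   patience=4, seed=0),
)

# profile a fresh unlabeled pool drawn from the same generator
unlabeled = manifest.sample(n=600, random_state=0).sort_index()
profile = profile_pool(model, ImageDataset(unlabeled, doms),
                       group_keys=("condition", "season"))
print(profile_report_markdown(profile))
print(
    "prop_* columns are percentages of predicted biological frames per "
    "group;\nn_excluded counts predicted multiple-event/debris frames, "
    "reported but excluded\nfrom the denominators."
)
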
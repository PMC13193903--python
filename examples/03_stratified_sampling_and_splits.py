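"""Stratified quota labeling, fixed splits, LOBO folds, fraction subsets.

Draws a labeling pool with an exact quota per class x breed x condition
stratum, then shows the fixed 80/10/10 split, leave-one-breed-out folds
with a 20 % validation share, and nested labeled-data fractions.
"""

import ifcmorph as im

h = im.HierarchySpec(
    n_bulls=6, ejaculates_per_bull={"fresh": 2, "frozen": 1},
    files_per_ejaculate=2, events_per_file=2000, seed=3,
)
manifest = im.generate_dataset(h, include_params=False)

pool = im.quota_sample(manifest, im.QuotaSpec(per_stratum_quota=20), rng_seed=0)
print(f"quota 20 x 10 classes x 3 breeds x 2 conditions -> {len(pool)} rows")

train, val, test = im.stratified_split(pool, im.SplitSpec(seed=1))
print(f"80/10/10 split: {len(train)}/{len(val)}/{len(test)}")

folds = im.lobo_folds(pool)
for f in folds:
    print(
        f"LOBO fold held_out={f['held_out']}: train {len(f['train'])}, "
        f"val {len(f['val'])} (20%), test {len(f['test'])}"
    )

subsets = im.fraction_subsets(train, rng_seed=2)
print("nested fractions:", {f: len(s) for f, s in sorted(subsets.items())})
# Every selection is deterministic at its seed; fraction subsets are nested
# so learning-curve differences reflect data volume, not sample identity.
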
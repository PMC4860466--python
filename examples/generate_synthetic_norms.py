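"""Generate a synthetic bilingual naming-norm dataset and inspect it.

Builds the three tables (stimuli, lexicon, responses) with the default study
structure — 73 objects x 68 features, 42 + 39 names, three groups — and
prints one object's name-agreement breakdown.
"""

from bilexmap import SynthConfig, generate_dataset

config = SynthConfig(divergence=0.3, seed=1)
dataset, manifest = generate_dataset(config)

print(f"objects: {len(dataset.object_ids)}, features: {len(dataset.feature_columns)}")
print(f"names: {len(dataset.words('A'))} in language A, "
      f"{len(dataset.words('B'))} in language B")

obj = dataset.object_ids[0]
for group, lang in [("mono_A", "A"), ("mono_B", "B"), ("bilingual", "A")]:
    row = dataset.agreements(group, lang).loc[obj]
    named = row[row > 0].sort_values(ascending=False)
    parts = ", ".join(f"{w}={v:.2f}" for w, v in named.items())
    print(f"{obj} / {group} naming in {lang}: {parts}")
# Agreement proportions per object sum to 1; the bilingual group's
# probabilities blend both languages' category boundaries, which is the
# ground-truth convergence the analyses should detect.
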
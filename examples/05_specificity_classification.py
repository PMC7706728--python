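"""Classify accessible sites into tissue-specificity classes.

Simulates a five-tissue RPM matrix with planted classes plus its
pairwise differential table, applies the rule-based classifier and
prints the recovery.
"""

from promarch import classify
from promarch.classify import DiffTable, cv_groups
from promarch.simulate import gen_class_matrix

matrix, diffs, truth = gen_class_matrix(noise_cv=0.2, effect=10.0, seed=4)
labels = classify(matrix, DiffTable(diffs), detect_threshold=8.0)

print(f"classified {len(labels)} sites across 5 tissues "
      f"(detection 8 RPM, FC > 3, padj < 0.01)")
counts = labels.map(lambda l: l.category).value_counts()
for cat, n in counts.items():
    print(f"  {cat:<20} {n}")
print(f"label recovery vs generator truth: {100 * (labels == truth).mean():.1f}%")

# CV grouping on the same matrix treated as a 5-sample expression panel:
groups = cv_groups(matrix)
print(f"CV groups: {dict((k, int(v)) for k, v in groups.value_counts().items())}")
# Sites below 8 RPM everywhere are never classified; a single dominant
# significantly different tissue gives 'specific'; 2-4 detected tissues
# separated from the rest give 'restricted'; detection in all five
# splits into uniform (<3-fold spread, no significant pair) vs biased.
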
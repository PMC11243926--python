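"""Dataset split and augmentation arithmetic for a detection corpus.

Reproduces the bookkeeping for a 4306-frame corpus: a 70/20/10
train/val/test split (floor, floor, remainder) and the growth from adding
two augmented copies of every training frame.
"""

from lizardtherm.dataset_tools import assign_split, augmented_total, split_counts

n_total = 4306
train, val, test = split_counts(n_total, (0.7, 0.2, 0.1))
print(f"{n_total} frames -> train {train}, val {val}, test {test}")

after = augmented_total(n_total, train, copies_per_image=2)
print(f"with 2 augmented copies per training frame: {n_total} -> {after}")

# a concrete deterministic assignment of frame ids
ids = [f"frame_{i:04d}" for i in range(20)]
tr, va, te = assign_split(ids, seed=1)
print(f"\n20 ids, seed 1: train {len(tr)}, val {len(va)}, test {len(te)}")
print("test set:", te)
# The same seed always yields the same partition, so a split can be
# reproduced exactly from its seed alone.
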
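"""Date retroposition events from presence/absence on dated species trees.

Each copy's carriers bracket its origin: no later than the carriers'
crown age, no earlier than the stem split above it (Dollo: one gain,
losses allowed). Uses the packaged primate and mammal trees with
literature split times.
"""
from retrotrace import (
    date_all, load_mammal_presence, load_mammal_tree,
    load_primate_presence, load_primate_tree,
)

print("primate-specific pseudogenes (Mya):")
print(date_all(load_primate_presence(), load_primate_tree()).to_string())
print("\nmammal-wide pseudogenes (Mya):")
print(date_all(load_mammal_presence(), load_mammal_tree()).to_string())
print("\n'open_ended' marks copies carried by every sampled taxon: the true "
      "origin may predate the root; the upper bound is the root's older "
      "age estimate. Losses name the branch where a copy was deleted.")
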
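"""Seed-match miRNA target prediction on the canonical site taxonomy.

A target carries a site where its sequence contains the reverse complement
of the miRNA seed (nt 2-7/2-8), optionally with an A anchor: 8mer >
7mer-m8 > 7mer-A1 > 6mer.  Coordinates are 0-based half-open on the target.
"""

from cernanet.io_formats import SequenceSet
from cernanet.target_prediction import find_sites, intersect_predictions, predict_pairs

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"
target = "G" * 20 + "CTACCTCA" + "G" * 20  # embeds the let-7 8mer site

for site in find_sites(LET7, target, "let-7", "demo-UTR"):
    print(f"{site.site_class} site at [{site.start}, {site.end}) -> "
          f"{target[site.start:site.end]}")

mirnas = SequenceSet(records={"let-7": LET7}, moltype="miRNA")
targets = SequenceSet(
    records={"hit": target, "hit_weak": "G" * 20 + "CTACCTC" + "G" * 20, "decoy": "G" * 47},
    moltype="transcript",
)
loose = predict_pairs(mirnas, targets, min_class="7mer-m8")
strict = predict_pairs(mirnas, targets, min_class="8mer")
consensus = intersect_predictions(loose, strict)
print(f"\n7mer-m8 threshold: {[p.target_id for p in loose]}; "
      f"8mer threshold: {[p.target_id for p in strict]}; "
      f"consensus: {[p.target_id for p in consensus]}")
print("the consensus of two thresholds keeps only the strongest, 8mer-supported pairing")
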
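"""Seed-match prediction of miRNA target sites.

A bespoke, deterministic predictor built on the canonical seed-site
taxonomy.  The seed region of a miRNA is nucleotides 2-8 (1-based, from the
5' end); a target transcript carries a site where its sequence contains the
reverse complement of (part of) the seed:

* ``8mer``     — reverse complement of nt 2-8, followed by an A opposite nt 1
* ``7mer-m8``  — reverse complement of nt 2-8
* ``7mer-A1``  — reverse complement of nt 2-7, followed by an A
* ``6mer``     — reverse complement of nt 2-7

Overlapping matches at one locus are reported at the highest class only.
Coordinates are 0-based, half-open on the target, which is scanned 5'->3'.
Two differently parameterized predictions (e.g. min_class 7mer-m8 vs 8mer)
can be intersected to emulate consensus calling across prediction tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from cernanet.io_formats import SequenceSet

SITE_CLASSES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
_CLASS_RANK = {c: i for i, c in enumerate(SITE_CLASSES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TargetSite:
    """One seed-match site; [start, end) on the target, 5'->3'."""

    miRNA_id: str
    target_id: str
    start: int
    end: int
    site_class: str

    def __post_init__(self) -> None:
        expect = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}[self.site_class]
        if self.end - self.start != expect:
            raise ValueError(f"{self.site_class} site must span {expect} nt, got {self.end - self.start}")


@dataclass
class TargetPair:
    """A miRNA-target relationship supported by >=1 site."""

    miRNA_id: str
    target_id: str
    sites: list[TargetSite] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def best_class(self) -> str:
        return max((s.site_class for s in self.sites), key=_CLASS_RANK.__getitem__)


def class_at_least(site_class: str, min_class: str) -> bool:
    return _CLASS_RANK[site_class] >= _CLASS_RANK[min_class]


def find_sites(mirna_seq: str, target_seq: str, mirna_id: str = "miRNA", target_id: str = "target") -> list[TargetSite]:
    """All seed-match sites of one miRNA on one target.

    The scan anchors on the 6mer core (reverse complement of seed nt 2-7)
    and upgrades each hit by checking the m8 match 5' of it and the A
    anchor 3' of it, so every locus is reported once at its highest class.
    """
    mir = mirna_seq.upper().replace("U", "T")
    tgt = target_seq.upper().replace("U", "T")
    for name, s in (("miRNA", mir), ("target", tgt)):
        bad = set(s) - set("ACGTN")
        if bad:
            raise ValueError(f"invalid {name} character(s): {sorted(bad)}")
    if len(mir) < 8:
        raise ValueError(f"miRNA must be >=8 nt, got {len(mir)}")

    core6 = reverse_complement(mir[1:7])  # seed nt 2-7
    m8_char = reverse_complement(mir[7])  # complement of seed nt 8, 5' of the core
    sites = []
    pos = tgt.find(core6)
    while pos != -1:
        has_m8 = pos > 0 and tgt[pos - 1] == m8_char
        has_a1 = pos + 6 < len(tgt) and tgt[pos + 6] == "A"
        if has_m8 and has_a1:
            sites.append(TargetSite(mirna_id, target_id, pos - 1, pos + 7, "8mer"))
        elif has_m8:
            sites.append(TargetSite(mirna_id, target_id, pos - 1, pos + 6, "7mer-m8"))
        elif has_a1:
            sites.append(TargetSite(mirna_id, target_id, pos, pos + 7, "7mer-A1"))
        else:
            sites.append(TargetSite(mirna_id, target_id, pos, pos + 6, "6mer"))
        pos = tgt.find(core6, pos + 1)
    return sites


def predict_pairs(mirnas: SequenceSet, targets: SequenceSet, min_class: str = "7mer-m8") -> list[TargetPair]:
    """All-vs-all site search keeping pairs whose best site reaches
    ``min_class``.  Output order is deterministic: (miRNA_id, target_id)."""
    if min_class not in SITE_CLASSES:
        raise ValueError(f"min_class must be one of {SITE_CLASSES}")
    if len(mirnas) == 0 or len(targets) == 0:
        raise ValueError("both sequence sets must be nonempty")
    pairs = []
    for mir_id in sorted(mirnas.records):
        for tgt_id in sorted(targets.records):
            sites = find_sites(mirnas[mir_id], targets[tgt_id], mir_id, tgt_id)
            if not sites:
                continue
            pair = TargetPair(mir_id, tgt_id, sites)
            if class_at_least(pair.best_class, min_class):
                pairs.append(pair)
    return pairs


def intersect_predictions(list_a: list[TargetPair], list_b: list[TargetPair]) -> list[TargetPair]:
    """Pairs present in both prediction lists, with site evidence merged."""
    by_key_b = {(p.miRNA_id, p.target_id): p for p in list_b}
    out = []
    for pa in list_a:
        key = (pa.miRNA_id, pa.target_id)
        if key not in by_key_b:
            continue
        merged = sorted(set(pa.sites) | set(by_key_b[key].sites), key=lambda s: (s.start, s.end, s.site_class))
        out.append(TargetPair(pa.miRNA_id, pa.target_id, merged))
    return out


def pairs_to_frame(pairs: list[TargetPair]):
    """Flatten pairs to a site-level table (one row per site)."""
    import pandas as pd

    rows = [
        (p.miRNA_id, p.target_id, s.start, s.end, s.site_class, p.best_class, p.n_sites)
        for p in pairs
        for s in p.sites
    ]
    return pd.DataFrame(rows, columns=["miRNA_id", "target_id", "start", "end", "site_class", "best_class", "n_sites"])
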
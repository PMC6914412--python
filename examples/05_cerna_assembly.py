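"""Sign-constrained ceRNA triplet assembly and planted-truth recovery.

An edge survives only if the pair is sequence-predicted, the two members are
DE in opposite directions, and their tumor-sample Pearson r is negative and
significant; triplets form through shared miRNAs.
"""

import pandas as pd

from cernanet.cerna_network import build_cerna, summarize_network
from cernanet.synthetic_data import SimulationConfig, generate, truth_report
from cernanet.target_prediction import predict_pairs

bundle = generate(
    SimulationConfig(n_cohorts=1, samples_per_cohort=(100, 25), n_triplets=10, seed=4)
)
pairs = predict_pairs(bundle.mirna_seqs, bundle.transcript_seqs)
de_records = pd.DataFrame(
    [
        {"feature_id": f,
         "feature_class": "miRNA" if f.startswith("mir") else "lncRNA" if f.startswith("L") else "mRNA",
         "direction": d}
        for f, d in bundle.truth.de_features.items()
    ]
)
net = build_cerna(
    de_records,
    [p for p in pairs if p.target_id.startswith("G")],
    [p for p in pairs if p.target_id.startswith("L")],
    {"mRNA": bundle.mrna, "lncRNA": bundle.lncrna, "miRNA": bundle.mirna},
)
s = summarize_network(net)
m = truth_report(bundle.truth, net)
print(f"ceRNA network: {s['n_lncRNA']} lncRNAs / {s['n_miRNA']} miRNAs / {s['n_mRNA']} mRNAs, "
      f"{s['n_edges']} edges, {s['n_triplets']} triplets")
print(net.triplets.head(3)[["lncRNA_id", "miRNA_id", "mRNA_id", "r_lnc_mi", "r_mi_m", "r_lnc_m"]]
      .round(2).to_string(index=False))
print(f"\nrecovery of the 10 planted triplets: precision {m.precision:.2f}, recall {m.recall:.2f}")
print("negative miRNA-partner and positive lncRNA-mRNA correlations are the ceRNA signature")
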
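"""Train the network on planted-motif data and decode its filters.

Generates the canonical synthetic conditions (41-nt windows, center U,
consensus UUCGAAUC planted at offset 12 in positives), trains a reduced
network, reports held-out AUC, then ranks convolutional filters by their
motif score M_s (mean max activation on positives minus negatives) and
shows the consensus the best filter recovered.
"""

import numpy as np
from sklearn.metrics import roc_auc_score

from rnamodnet.dataset import make_splits
from rnamodnet.interpret import motif_reports
from rnamodnet.network import NetworkConfig, build_network, train
from rnamodnet.rbpmatch import compare_pwms
from rnamodnet.synthetic import consensus_pwm, default_spec, generate

windows, truth = generate(default_spec(n_pos=400, n_neg=400, seed=1))
labels = [w.label for w in windows]
manifest = make_splits(list(range(len(windows))), labels, test_fraction=0.2,
                       k=5, seed=1)
tr = [windows[i] for i in manifest.train_ids]
te = [windows[i] for i in manifest.test_ids]

cfg = NetworkConfig(conv_filters=64, lstm_units=32, fc_units=64,
                    batch_size=32, learning_rate=3e-3, max_epochs=8, seed=1)
net = train(build_network(cfg), tr, te)

auc = roc_auc_score([w.label for w in te], net.predict(te))
print(f"held-out AUC: {auc:.3f}   (planted motif -> near-perfect separation)")

pos = [w for w in te if w.label == 1]
neg = [w for w in te if w.label == 0]
top = motif_reports(net, pos, neg)[:5]
target = consensus_pwm("UUCGAAUC")
print("\ntop filters by motif score M_s:")
for r in top:
    off, sim = compare_pwms(r.pwm, target)
    print(f"  filter {r.filter_id:3d}  M_s={r.motif_score:.3f}  "
          f"p={r.p_value:.1e}  consensus={r.pwm.consensus()}  "
          f"match-to-plant r={sim:.2f}")
print("\nM_s > 0 with small p means the filter fires preferentially on "
      "modified windows;\nthe recovered consensus should echo UUCGAAUC.")
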
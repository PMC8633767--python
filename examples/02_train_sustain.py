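"""Train the SUSTAIN network on a 1D and a 2D task and inspect what it learns.

Prints the per-session learning curve, the final cluster inventory, and the
attention weights.  On 1D tasks attention concentrates on the relevant
dimension and two clusters (one prototype per category) suffice; on 2D
tasks attention stays split and several clusters per category tile the
elongated category distributions.
"""

import numpy as np

from ratcat import build_task
from ratcat.sustain import DEFAULT_PARAMS, cluster_categories, run_training

for rot in (0, 45):
    task = build_task(rot)
    res = run_training(task, DEFAULT_PARAMS, rng=42)
    cats = cluster_categories(res.assoc)
    lam = res.lam_trace[-80:].mean(axis=0)
    print(f"rotation {rot}° ({task.task_class} task)")
    print("  session accuracy:", np.round(res.session_acc, 2))
    print(f"  clusters: {res.n_clusters} total "
          f"({(cats == 0).sum()} category A, {(cats == 1).sum()} category B)")
    print(f"  final attention  lambda_x={lam[0]:.2f}  lambda_y={lam[1]:.2f}")
    print()

print("Accuracy rises from near-chance toward >0.85; the 1D run ends with")
print("attention concentrated on x and ~2 clusters, the 2D run with balanced")
print("attention and several clusters per category.")
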
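"""Computational screen of random three-node networks for boundary precision.

Samples three-node Hill networks with a graded morphogen input into nodes 1
and 2, keeps those realising a discontinuous bistable switch across the
tissue, and relates boundary width to minimum-action-path curvature, signal
sensitivity and the effective use of the third node.  Writes
results/screen_records.csv, results/screen_summary.json and
results/topologies.csv.  Pass a sample count as the first argument to
rescale (default 2000).
"""

import json
import sys
import warnings

from grnprecision.screen import (
    ScreenConfig,
    evaluate_wildtype_network,
    rank_topologies,
    run_screen,
)

warnings.simplefilter("ignore")

n_samples = int(sys.argv[1]) if len(sys.argv) > 1 else 4000
cfg = ScreenConfig(n_samples=n_samples, seed=1)
res = run_screen(cfg, progress=True)
res.records.to_csv("results/screen_records.csv", index=False)
print(f"accepted {res.summary['n_accepted']} / {n_samples} networks")
print("Spearman(width, curvature) =", round(res.summary.get("spearman_width_curvature", float('nan')), 3))
print("Spearman(width, sensitivity) =", round(res.summary.get("spearman_width_sensitivity", float('nan')), 3))

tab = rank_topologies(res)
tab.to_csv("results/topologies.csv", index=False)
n_top = max(4, len(tab) // 10)
top = tab.head(n_top)
print(f"top {n_top} topologies: x2 -| x3 present in {top['x2_represses_x3'].mean():.0%} "
      f"(vs {tab['x2_represses_x3'].mean():.0%} overall); "
      f"x3 -| x2 present in {top['x3_represses_x2'].mean():.0%} "
      f"(vs {tab['x3_represses_x2'].mean():.0%} overall)")

wt = evaluate_wildtype_network(cfg)
res.summary["wildtype"] = {k: v for k, v in wt.items() if k != "index"}
if wt["accepted"]:
    med = float(res.accepted["curvature"].median())
    print(f"neural-tube network accepted; curvature {wt['curvature']:.3f} vs accepted median {med:.3f}")

with open("results/screen_summary.json", "w") as fh:
    json.dump(res.summary, fh, indent=2, default=float)
print("wrote results/screen_records.csv, results/topologies.csv, results/screen_summary.json")
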
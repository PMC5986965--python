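"""Back-project discriminative weights to connections, seeds, networks.

From the full-cohort feature chain: per-connection loading-magnitude
weights, half-split seed weights, the strengthened/weakened x
motor/non-motor partition, and per-network involvement (raw and
normalized by network size).  Also exports BrainNet-style .node/.edge
files for visualization.  All tables land under results/.
"""

import numpy as np
import pandas as pd

from common import ATLAS, RESULTS, STUDY, study_cohort
from fcstage.atlas import write_node_file
from fcstage.attribution import (
    connection_weights,
    direction_partition,
    network_involvement,
    seed_weights,
    write_edge_file,
)
from fcstage.features import FeatureChain


def main() -> None:
    x_pre, x_post, participants, truth = study_cohort()
    chain = FeatureChain().fit(x_pre, x_post)
    selected = chain.selection.selected_indices
    s = STUDY.n_seeds

    conn = connection_weights(chain.basis, selected, s)
    part = direction_partition(x_pre, x_post, selected, ATLAS)
    planted = set(truth.planted_indices(s).tolist())

    frame = conn.as_frame(ATLAS)
    frame["direction"] = part.direction
    frame["class"] = np.where(part.motor, "motor", "non-motor")
    frame["planted"] = [k in planted for k in conn.connection_indices]
    frame = frame.sort_values("weight", ascending=False)
    frame.to_csv(RESULTS / "connection_weights.tsv", sep="\t", index=False,
                 float_format="%.4f")

    print("strengthened/weakened x motor/non-motor breakdown:")
    print(part.summary().to_string())
    mask = frame["planted"].to_numpy()
    print(f"\nplanted connections' mean weight {frame['weight'][mask].mean():.4f} vs "
          f"{frame['weight'][~mask].mean():.4f} for the rest")

    sw = seed_weights(conn, ATLAS)
    seed_frame = sw.as_frame(ATLAS)
    seed_frame.to_csv(RESULTS / "seed_weights.tsv", sep="\t", index=False,
                      float_format="%.4f")
    print("\ntop five weighted seeds:")
    print(seed_frame.head(5).to_string(index=False))

    inv_raw = network_involvement(selected, ATLAS)
    inv_norm = network_involvement(selected, ATLAS, normalize=True)
    inv = pd.DataFrame({
        "network": list(inv_raw),
        "raw_count": list(inv_raw.values()),
        "normalized": [inv_norm[n] for n in inv_raw],
    })
    inv.to_csv(RESULTS / "network_involvement.tsv", sep="\t", index=False,
               float_format="%.3f")
    print("\nnetwork involvement (raw counts sum to twice the selected connections):")
    print(inv.to_string(index=False))

    write_node_file(ATLAS, RESULTS / "seeds.node", sizes=sw.cumulative_weight)
    write_edge_file(conn, part.direction, s, RESULTS / "connections.edge")
    print(f"\nBrainNet exports -> {RESULTS}/seeds.node, {RESULTS}/connections.edge")


if __name__ == "__main__":
    main()
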
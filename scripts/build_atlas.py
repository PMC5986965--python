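"""Regenerate the packaged synthetic-coordinate default atlas.

The default template's network memberships and per-network seed counts
follow the published 13-network / 236-seed parcellation; the coordinate
list itself is not redistributed, so deterministic synthetic MNI-like
coordinates are generated instead (seeded; rerunning reproduces the
shipped file byte for byte).  Coordinates feed visualization exports
only — no pipeline computation reads them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from fcstage.atlas import DEFAULT_NETWORKS

OUT = Path(__file__).resolve().parents[1] / "src" / "fcstage" / "data" / "atlas_236_synthetic.tsv"

# MNI-like bounding boxes: cerebrum for cortical/subcortical networks,
# a lower posterior box for the cerebellar seeds.
CEREBRUM = ((-68, 68), (-100, 68), (-40, 74))
CEREBELLUM = ((-40, 40), (-85, -45), (-50, -20))

ABBREV = {
    "Sensory/somatomotor hand": "SMhand",
    "Sensory/somatomotor mouth": "SMmouth",
    "Cingulo-opercular task control": "CinguloOperc",
    "Auditory": "Auditory",
    "Default mode": "DMN",
    "Memory retrieval": "MemRetr",
    "Ventral attention": "VentAttn",
    "Visual": "Visual",
    "Fronto-parietal task control": "FrontoParietal",
    "Salience": "Salience",
    "Subcortical": "Subcortical",
    "Cerebellar": "Cerebellar",
    "Dorsal attention": "DorsAttn",
}


def main() -> None:
    rng = np.random.default_rng(20180529)
    rows = []
    for network, _color, count in DEFAULT_NETWORKS:
        box = CEREBELLUM if network == "Cerebellar" else CEREBRUM
        for i in range(count):
            x, y, z = (rng.uniform(lo, hi) for lo, hi in box)
            rows.append(
                {
                    "x_mm": round(float(x), 1),
                    "y_mm": round(float(y), 1),
                    "z_mm": round(float(z), 1),
                    "network": network,
                    "label": f"{ABBREV[network]}_{i + 1:02d}",
                    "radius_mm": 5.0,
                }
            )
    df = pd.DataFrame(rows)
    OUT.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT, sep="\t", index=False)
    print(f"wrote {OUT} ({len(df)} seeds, {df['network'].nunique()} networks)")


if __name__ == "__main__":
    main()
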
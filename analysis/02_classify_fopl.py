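"""Assign multiple-traffic-light colours and the healthy/unhealthy flag.

Reads results/databank.csv, classifies every item per 100 g (drinks under
the lower drink cut-offs), writes results/fopl.csv, and prints the
traffic-light and healthy/unhealthy breakdown by Nova group.
"""

from pathlib import Path

import pandas as pd

from micronova.core import load_thresholds, read_item_table
from micronova.fopl import classify_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    items = read_item_table(OUT / "databank.csv")
    fopl = classify_table(items, load_thresholds())
    combined = items[["item_id", "nova", "is_drink"]].join(fopl)
    combined.to_csv(OUT / "fopl.csv", index=False)

    print(f"classified {len(items)} items per 100 g")
    healthy = pd.crosstab(items["nova"], fopl["healthy"].map({True: "healthy", False: "unhealthy"}))
    print("\nHealthy (no red light) vs unhealthy by Nova group:")
    print(healthy.to_string())
    share = (healthy["healthy"] / healthy.sum(axis=1) * 100).round(1)
    print("\n% healthy per group:")
    print(share.to_string())


if __name__ == "__main__":
    main()
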
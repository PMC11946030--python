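"""Compute % RNI contributions and composite scores on both bases.

Reads results/databank.csv, scores every item against the female RNI table
per 100 g and per 100 kcal (zero-energy items excluded from the latter),
writes results/contributions_<basis>.csv, and prints composite medians by
Nova group together with the zero-content proportions.
"""

from pathlib import Path

import pandas as pd

from micronova import registry
from micronova.core import load_rni_table, read_item_table
from micronova.scoring import contribution_table, zero_content_proportions

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    items = read_item_table(OUT / "databank.csv")
    rni = load_rni_table(sex="female")

    for basis in ("per100g", "per100kcal"):
        contrib = contribution_table(items, rni, basis)
        combined = items[["item_id", "nova", "is_drink"]].join(contrib)
        combined.to_csv(OUT / f"contributions_{basis}.csv", index=False)
        n_excl = int(contrib["excluded_zero_energy"].sum())
        print(f"\n=== {basis} (n = {len(items) - n_excl}, {n_excl} zero-energy excluded)")
        med = (
            combined[~combined["excluded_zero_energy"]]
            .groupby("nova")["composite18"]
            .median()
            .round(1)
        )
        print("composite (/18) median by Nova group:")
        print(med.to_string())

    zero = pd.concat(
        [zero_content_proportions(items, k) for k in registry.RNI_KEYS], axis=1
    ).T
    zero.index.name = "micronutrient"
    zero.round(3).to_csv(OUT / "zero_content.csv")
    print("\nzero-content proportion (overall), top 5 micronutrients:")
    print(zero["overall"].sort_values(ascending=False).head().round(3).to_string())


if __name__ == "__main__":
    main()
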
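"""Pollution indices: per-batch single-factor P_i with class counts, and
per-material Nemerow P_N (mean-concentration mode).

Reads results/batches.csv, writes results/pollution_batch.csv and
results/pollution_material.csv.
"""

from pathlib import Path

import pandas as pd

from pte_risk import read_batches, substitute_nd
from pte_risk.pollution import batch_pollution_table, material_pollution

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = substitute_nd(read_batches(RESULTS / "batches.csv"))
    table = batch_pollution_table(records)
    table.to_csv(RESULTS / "pollution_batch.csv", index=False)

    per_batch = table.groupby("batch_id")["P_i"].max()
    print(f"batches with any P_i > 1: {(per_batch > 1).sum()} of {per_batch.size}")
    print(f"  heavy (P_i > 3): {(per_batch > 3).sum()}")
    print(f"  moderate (2 < P_i <= 3): {((per_batch > 2) & (per_batch <= 3)).sum()}")
    print(f"  slight (1 < P_i <= 2): {((per_batch > 1) & (per_batch <= 2)).sum()}")

    rows = []
    by_material: dict[str, list] = {}
    for r in records:
        by_material.setdefault(r.material, []).append(r)
    for material in sorted(by_material):
        pn = material_pollution(by_material[material], mode="mean")
        rows.append(
            {
                "material": material,
                "category": by_material[material][0].category.value,
                "P_N": pn.value,
                "pn_class": pn.klass,
            }
        )
    mat = pd.DataFrame(rows)
    mat.to_csv(RESULTS / "pollution_material.csv", index=False)
    above = mat[mat.P_N > 0.7].sort_values("P_N", ascending=False)
    print(f"materials above alert level (P_N > 0.7): {len(above)}")
    for _, row in above.head(8).iterrows():
        print(f"  {row.material:<40} P_N={row.P_N:.2f} ({row.pn_class})")


if __name__ == "__main__":
    main()
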
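"""Deterministic health risk per material: THQ per element, HI, CR for the
carcinogenic elements, with risk-band labels.

Reads results/batches.csv + results/doses.yaml, writes results/risk.csv.
"""

from pathlib import Path

import yaml

from pte_risk import DoseRegistry, read_batches, substitute_nd
from pte_risk.health_risk import risk_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = substitute_nd(read_batches(RESULTS / "batches.csv"))
    doses = DoseRegistry(yaml.safe_load((RESULTS / "doses.yaml").read_text()))
    table = risk_table(records, doses)
    table.to_csv(RESULTS / "risk.csv", index=False)
    print(f"materials assessed: {len(table)}; HI >= 1: {(table.HI >= 1).sum()}")
    for cat, grp in table.groupby("category"):
        worst = grp.sort_values("HI", ascending=False).iloc[0]
        print(
            f"  {cat:<16} highest HI {worst.HI:.3g} ({worst.material}); "
            f"highest CR_total {grp.CR_total.max():.3g}"
        )


if __name__ == "__main__":
    main()
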
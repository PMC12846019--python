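"""Descriptive survey statistics: per element x category detection rates,
exceedance rates, ranges and means after LOD/2 substitution.

Reads results/batches.csv, writes results/descriptive.csv.
"""

from pathlib import Path

from pte_risk import read_batches, substitute_nd
from pte_risk.descriptive import summary_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = substitute_nd(read_batches(RESULTS / "batches.csv"))
    table = summary_table(records)
    table.to_csv(RESULTS / "descriptive.csv", index=False)
    overall = table[table.group == "overall"]
    print(f"overall detection rate: {overall.detection_rate_pct.mean():.1f}%")
    for _, row in overall.iterrows():
        print(
            f"  {row.element:>2}: range {row.range_lo:.2f}-{row.range_hi:.2f} mg/kg, "
            f"mean {row['mean']:.3g} +- {row.sd:.3g}, detected {row.detection_rate_pct:.1f}%, "
            f"exceeding {row.exceedance_rate_pct:.1f}%"
        )


if __name__ == "__main__":
    main()
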